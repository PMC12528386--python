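# Methods

## Measurement model

A 2D projection image of a Gram-negative envelope shows the inner and
outer membrane as two roughly parallel dark ridges. We model each ridge
cross-section as a single Gaussian dip (at typical TEM magnifications a
membrane reads as one dark band, not a railroad-track bilayer), and define
the intermembrane distance at an arc position as the distance between the
two dip centers along the local envelope normal. All physical scales are
nm; the only unit conversion is the isotropic pixel size (default
0.3266 nm/px, matching a 200-keV TEM at 45,000× nominal magnification).
Anisotropic rasters are rejected.

### Enhancement and segmentation

The image is smoothed with a Gaussian of σ = 3 nm and then passed through
a variance filter of circular radius 10 nm (both boundaries half-sample
symmetric, so edges are not dimmed and the Gaussian conserves the mean
exactly). The "3 nm" and "10 nm" follow the conventions of the named
ImageJ/FIJI operations these parameters mirror: Gaussian Blur takes a
sigma, Variance takes a radius. Membrane pixels are bright in the variance
image; Otsu's threshold (computed inside the ROI when one is given) makes
the step deterministic where an interactive tool would be used, and a
fixed-threshold override exists. Components smaller than a 50 nm × 6 nm
rectangle are removed as speckle. The variance image serves segmentation
only: peak positions are always measured on the Gaussian-filtered
intensity, because variance filtering destroys the dip-center geometry the
distance definition relies on. The variance filter is computed as FFT
moving moments E[x²] − E[x]² on mean-shifted intensities, which matches a
direct per-window enumeration to ~1e-13 relative.

### Centerline and straightening

The traced path is the *mid-envelope* centerline, not either membrane
alone: the mask is morphologically closed with a Euclidean disk (radius
20 nm ≥ half the expected separation, implemented via distance transforms)
so the two ridges merge into one band, the band is skeletonized, spurs
shorter than a quarter of the minimum path length are pruned, branches are
split at junctions, and each remaining branch is ordered by greedy
walking. Because the medial axis stops about half a band-width short of
the band ends, open paths are extended along their (smoothed) end tangents
to the band boundary and re-smoothed; without this the first and last
50-nm segments of every cell would be lost. The ordered pixel chain is
smoothed with a σ = 3 nm Gaussian along the sequence to obtain subpixel
positions. Closed contours (whole-cell outlines) are traversed as cycles
with wraparound smoothing; the seam point is arbitrary.

Straightening resamples the Gaussian-filtered image by bilinear
interpolation at 1-px steps along the local unit normal, offsets in
±40 nm (covers separations to ~60 nm plus margins). Normals come from a
10-nm-smoothed tangent; bilinear interpolation is adequate at 0.33 nm/px
(the dips span ~12 px). The normal is the +90° rotation of the tangent, so
the sign of the offset axis is consistent within a path but globally
arbitrary; distances are label-independent.

### Pole exclusion

Measurements are restricted to cylindrical midsections. User ROI boxes
take precedence (mirroring manually drawn measurement boxes); otherwise
points where the local curvature — finite differences of the tangent angle
averaged over a 20-nm window — exceeds 1/500 nm⁻¹ are removed and the path
split. The cutoff excludes caps of radius < 500 nm, i.e. the poles of
cells up to ~1 µm wide, while keeping gentle envelope undulations.
Fragments shorter than one segment (50 nm) are dropped.

### Segment averaging and peak pairing

The ribbon is cut into consecutive non-overlapping windows of
floor(50 nm / pixel size) columns (153 columns = 49.97 nm at the default
calibration; the trailing remainder is discarded), and each window's
columns are averaged into one cross-profile before peak detection —
averaging first suppresses noise coherently and is our reading of a
"per-50-nm-segment average"; averaging per-column peak positions instead
is noted as an alternative but not implemented. After polarity
normalization (membranes as maxima) and affine normalization to the
profile's dynamic range, local maxima are ranked by prominence; the two
most prominent peaks at least one membrane FWHM (6 nm) apart are selected.
Each center is refined as the zero crossing of the first difference
between the two gradient samples flanking the maximum, by linear
interpolation — for the ~4-nm-σ effective dips this bracketing interval
lies deep inside the locally linear part of the derivative, giving
~0.01-px accuracy on noiseless profiles (a 3-point parabolic fit is
available as an alternative). QC replaces manual curation: a segment fails
with an explicit reason if two peaks are not found, a peak sits at the
profile edge, the smaller prominence is below 20% of the dynamic range, or
the distance falls outside 12–60 nm. Failures never abort a batch; they
are rows with `qc_pass = false`.

### Statistics

Group summaries use linear-interpolation quartiles (NumPy convention,
stated here because conventions differ) and whiskers clipped to the most
extreme point within 1.5 IQR of the corresponding quartile. The default
two-sample test is the pooled-variance Student t (df = n₁ + n₂ − 2), with
Welch available. Group comparison pools every qc-passing segment as one
observation ("points" mode, matching the convention where n is the number
of measurement points); this ignores within-cell correlation, so a
per-cell-mean mode is provided for sensitivity analysis but is not the
default. Replicate structure can be carried in the table's labels but is
not modeled. Pearson's r uses the t-based two-tailed p with n − 2 degrees
of freedom.

## Synthetic data

The generator renders what the measurement assumes, with analytic truth:

* separation d(s) = baseline + wrinkle·sin(2πs/λ) + rough(s), with rough a
  moving-average-smoothed Gaussian process (sd default 0.5 nm, correlation
  length 25 nm) mimicking within-cell heterogeneity without unphysical
  high-frequency jitter;
* membrane ridges as Gaussian dips (FWHM default 6 nm, within the 5–8 nm
  band a projected membrane occupies) centered at ±d(s)/2 along the
  midline normal; dark-on-bright polarity by default;
* defaults: 500-nm envelope (ten 50-nm segments), baseline 24 nm, wrinkle
  amplitude 1 nm with 200-nm wavelength, contrast 1, pixel 0.3266 nm,
  optional blur and additive white noise (cohort studies here use noise at
  15% of ridge depth);
* cohorts: per-cell baselines drawn from a truncated normal (30 cells per
  group in the headline comparison, between-cell sd 1 nm), per-cell seeds
  derived deterministically from the cohort seed;
* optionally a closed spherocylinder contour (straight sides + semicircular
  caps) for pole-exclusion tests.

Rendering evaluates the distance from every pixel to densely sampled
(0.1-nm) membrane polylines via a KD-tree; quantization is far below the
0.01-nm render-fidelity budget verified by dense profile scans.

What the generator does **not** emulate: CTF/defocus fringes, dose and
detector artifacts, montage blending seams, cytoplasmic and surface
texture, neighbouring cells, and membrane invaginations. Passing tests
therefore demonstrate correctness of the geometry, the estimator and the
statistics under the stated image model — not robustness to every real
imaging artifact; on real data the QC rates, not the estimator, are
expected to absorb most of the difference.

## Numerical choices and edge cases

* Quantities configured in nm are converted once via the pixel size;
  defaults are stated in `PipelineConfig`.
* Filters: reflective boundaries; FFT variance moments on mean-shifted
  data avoid cancellation.
* Ties/degeneracies: constant images fail segmentation with a distinct
  error; a flat or single-peak profile fails QC rather than raising;
  identical groups give t = 0, p = 1 (the 0/0 case is defined that way).
* Segment spans equal the integer-pixel window (49.97 nm at default
  calibration), not exactly 50 nm; indices start at 0 at each fragment
  start.
* Determinism: one integer seed fans out to per-cell render seeds; reruns
  reproduce CSV/JSON outputs byte for byte (floats are serialized with
  shortest-round-trip representations).

## Problem sizes used in the shipped checks

The cohort comparison is run at 30 cells per group with 500-nm envelopes
(~270 segments per group); filter-oracle checks use 50 random 32×32
images; geometry checks use a full 2π annulus of radii 400/424 nm at
0.5 nm/px and a spherocylinder with 300-nm caps at 0.6 nm/px. These sizes
were chosen to keep every quantity's sampling error well inside its
assertion tolerance.

## Known limitations

* The two-peak model assumes the membranes are the two dominant ridges in
  the ±40-nm window; heavy surface layers or plasmolysis would need wider
  bounds or masking.
* Point-level pooling overstates the effective n when within-cell
  correlation is strong; use the per-cell mode for a conservative test.
* Curvature-based pole exclusion assumes poles are the only high-curvature
  regions; strongly bent (banana-shaped) cells should be handled with ROI
  boxes instead.
* MRC input is not implemented; images are exchanged as TIFF.
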