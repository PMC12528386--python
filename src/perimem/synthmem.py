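"""Synthetic cryo-EM-like envelope images with analytic ground truth.

Real raw montages of the envelope images this pipeline was designed for are
not publicly deposited, so every downstream stage is validated against
renders produced here: two roughly parallel dark ridges (the inner and
outer membrane), each with a Gaussian cross-section of known FWHM, centered
on analytically known midlines with a known center-to-center separation
``d(s)``. A cell appears either as an open cylindrical side strip (the
default — the part of a cell a measurement box would cover) or, when
``cap_radius_nm`` is set, as a closed spherocylinder contour whose
semicircular poles exercise pole exclusion.

Separation along the envelope is

    d(s) = baseline + wrinkle_amp * sin(2*pi*s/wrinkle_wavelength) + rough(s)

where ``rough`` is a moving-average-smoothed Gaussian process (correlation
length ``rough_corr_nm``) emulating within-cell heterogeneity in periplasmic
thickness without high-frequency jitter. At each arc position the two
membrane midlines are offset by ``±d(s)/2`` along the local unit normal, so
the separation along the shared normal equals ``d(s)`` by construction.

Membranes are rendered as single Gaussian dips (dark on bright by default,
the cryo-EM polarity): at the emulated magnification each membrane reads as
one dark band, which keeps the two-peak distance model well posed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError
from .imgio import DEFAULT_PIXEL_SIZE_NM, CalibratedImage

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: arc-length step (nm) used both to densify rendered midlines and to sample
#: the ground truth; small enough that polyline quantization is far below
#: the 0.01-nm render-fidelity budget.
_DS_NM = 0.1

#: margin (nm) between the envelope and the image border; covers the default
#: straightening half-width plus filter support.
_MARGIN_NM = 48.0


@dataclass(frozen=True)
class EnvelopeSpec:
    """Parameters of one synthetic envelope render.

    All lengths in nm. ``length_nm`` is the arc length of the rendered side
    strip (for spherocylinders, of *each* straight side). ``contrast`` is the
    ridge depth relative to the background level of 1.0; ``noise_sd`` is the
    additive white-noise standard deviation in the same units.
    """

    length_nm: float = 500.0
    baseline_sep_nm: float = 24.0
    wrinkle_amp_nm: float = 1.0
    wrinkle_wavelength_nm: float = 200.0
    rough_sd_nm: float = 0.5
    rough_corr_nm: float = 25.0
    path_curvature: float = 0.0  # 1/nm; 0 = straight midline
    membrane_fwhm_nm: float = 6.0
    contrast: float = 1.0
    noise_sd: float = 0.0
    blur_sigma_nm: float = 0.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    orientation_deg: float = 0.0
    polarity: str = "dark"
    cap_radius_nm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_nm < 100.0:
            raise ParameterError(
                f"length_nm must be >= 100 (two 50-nm segments), got {self.length_nm}"
            )
        if not self.baseline_sep_nm > self.membrane_fwhm_nm:
            raise ParameterError(
                "baseline_sep_nm must exceed membrane_fwhm_nm for the two peaks "
                f"to be resolvable, got {self.baseline_sep_nm} <= {self.membrane_fwhm_nm}"
            )
        if not self.wrinkle_amp_nm + 3.0 * self.rough_sd_nm < self.baseline_sep_nm / 2.0:
            raise ParameterError(
                "wrinkle_amp_nm + 3*rough_sd_nm must stay below baseline_sep_nm/2 "
                "so the separation remains positive"
            )
        for name in ("wrinkle_wavelength_nm", "rough_corr_nm", "membrane_fwhm_nm",
                     "contrast", "pixel_size_nm"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("wrinkle_amp_nm", "rough_sd_nm", "noise_sd", "blur_sigma_nm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.polarity not in ("dark", "bright"):
            raise ParameterError(f"polarity must be 'dark' or 'bright', got {self.polarity!r}")
        if self.cap_radius_nm is not None and self.cap_radius_nm <= self.baseline_sep_nm:
            raise ParameterError("cap_radius_nm must exceed the membrane separation")


@dataclass
class GroundTruthEnvelope:
    """Analytic truth accompanying a rendered envelope.

    ``im_rc`` / ``om_rc`` / ``mid_rc`` are subpixel (row, col) coordinates of
    the inner-membrane, outer-membrane and mid-envelope curves at the arc
    samples ``s_nm``; ``d_nm`` is the center-to-center separation along the
    shared normal. ``segment_true_means`` maps each full 50-nm segment index
    to the mean of ``d_nm`` over that segment. For spherocylinders,
    ``cap_centers_rc`` holds the two cap-center coordinates and
    ``cap_ranges_s_nm`` the arc intervals occupied by the caps.
    """

    s_nm: np.ndarray
    im_rc: np.ndarray
    om_rc: np.ndarray
    mid_rc: np.ndarray
    d_nm: np.ndarray
    pixel_size_nm: float
    segment_true_means: dict[int, float] = field(default_factory=dict)
    cap_centers_rc: np.ndarray | None = None
    cap_ranges_s_nm: list[tuple[float, float]] = field(default_factory=list)
    closed: bool = False

    def in_cap(self, row: float, col: float, pad_nm: float = 0.0) -> bool:
        """Whether a pixel-coordinate point lies in a polar-cap region.

        A point belongs to a cap if its projection onto the cell axis (the
        segment joining the two cap centers) falls outside the straight-side
        span, with an optional extra pad in nm.
        """
        if self.cap_centers_rc is None:
            return False
        a, b = self.cap_centers_rc
        ab = b - a
        t = np.dot(np.array([row, col]) - a, ab) / np.dot(ab, ab)
        pad = pad_nm / self.pixel_size_nm / np.linalg.norm(ab)
        return t < pad or t > 1.0 - pad


def _roughness(s: np.ndarray, sd: float, corr_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Moving-average-smoothed Gaussian roughness with the stated sd."""
    if sd == 0.0:
        return np.zeros_like(s)
    ds = s[1] - s[0]
    win = max(1, int(round(corr_nm / ds)))
    white = rng.standard_normal(s.size + win)
    smooth = np.convolve(white, np.ones(win) / win, mode="valid")[: s.size]
    # MA of unit white noise has sd 1/sqrt(win); rescale analytically so the
    # marginal sd equals the requested value regardless of the draw.
    return smooth * (sd * np.sqrt(win))


def _separation(spec: EnvelopeSpec, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d = spec.baseline_sep_nm + spec.wrinkle_amp_nm * np.sin(
        2.0 * np.pi * s / spec.wrinkle_wavelength_nm
    )
    d = d + _roughness(s, spec.rough_sd_nm, spec.rough_corr_nm, rng)
    return d


def _open_midline(spec: EnvelopeSpec, s: np.ndarray) -> np.ndarray:
    """Midline (x, y) of an open strip: straight or a constant-curvature arc."""
    k = spec.path_curvature
    if k == 0.0:
        return np.column_stack([s, np.zeros_like(s)])
    r = 1.0 / k
    return np.column_stack([r * np.sin(s / r), r * (1.0 - np.cos(s / r))])


def _spherocylinder_midline(spec: EnvelopeSpec, s: np.ndarray, radius: float, length: float):
    """Closed spherocylinder contour traversed counter-clockwise.

    Returns (xy, cap_mask, cap_centers_xy). Arc layout: top side (length),
    right cap (pi*R), bottom side (length), left cap (pi*R).
    """
    cap = np.pi * radius
    xy = np.empty((s.size, 2))
    cap_mask = np.zeros(s.size, dtype=bool)
    b1, b2, b3 = length, length + cap, 2 * length + cap
    for i, si in enumerate(s):
        if si < b1:  # top side, left to right
            xy[i] = (si, radius)
        elif si < b2:  # right cap
            a = np.pi / 2 - (si - b1) / radius
            xy[i] = (length + radius * np.cos(a), radius * np.sin(a))
            cap_mask[i] = True
        elif si < b3:  # bottom side, right to left
            xy[i] = (length - (si - b2), -radius)
        else:  # left cap
            a = -np.pi / 2 - (si - b3) / radius
            xy[i] = (radius * np.cos(a), radius * np.sin(a))
            cap_mask[i] = True
    centers = np.array([[length, 0.0], [0.0, 0.0]])
    return xy, cap_mask, centers


def _normals(xy: np.ndarray, closed: bool) -> np.ndarray:
    """Unit normals from central-difference tangents (+90-degree rotation)."""
    if closed:
        t = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
    else:
        t = np.gradient(xy, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n = np.column_stack([-t[:, 1], t[:, 0]])
    return n


def _segment_means(s: np.ndarray, d: np.ndarray, seg_len: float = 50.0) -> dict[int, float]:
    out: dict[int, float] = {}
    n_full = int(np.floor((s[-1] + (s[1] - s[0]) / 2) / seg_len))
    for i in range(n_full):
        sel = (s >= i * seg_len) & (s < (i + 1) * seg_len)
        if sel.any():
            out[i] = float(d[sel].mean())
    return out


def generate_envelope(spec: EnvelopeSpec) -> tuple[CalibratedImage, GroundTruthEnvelope]:
    """Render one envelope and its analytic ground truth.

    Identical spec (including seed) gives bit-identical output; with
    ``noise_sd == 0`` and ``blur_sigma_nm == 0`` the render is an exact
    deterministic function of the geometry.
    """
    rng = np.random.default_rng(spec.seed)
    closed = spec.cap_radius_nm is not None
    if closed:
        total = 2.0 * spec.length_nm + 2.0 * np.pi * spec.cap_radius_nm
        s = np.arange(0.0, total, _DS_NM)
        mid_xy, cap_mask, cap_centers = _spherocylinder_midline(
            spec, s, spec.cap_radius_nm, spec.length_nm
        )
    else:
        s = np.arange(0.0, spec.length_nm + _DS_NM / 2, _DS_NM)
        mid_xy = _open_midline(spec, s)
        cap_mask, cap_centers = None, None

    d = _separation(spec, s, rng)
    n = _normals(mid_xy, closed)
    im_xy = mid_xy - 0.5 * d[:, None] * n
    om_xy = mid_xy + 0.5 * d[:, None] * n

    # global rotation, then translation into the image frame with a margin
    th = np.deg2rad(spec.orientation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = [p @ rot.T for p in (mid_xy, im_xy, om_xy)]
    if cap_centers is not None:
        cap_centers = cap_centers @ rot.T
    lo = np.min([p.min(axis=0) for p in pts[1:]], axis=0) - _MARGIN_NM
    hi = np.max([p.max(axis=0) for p in pts[1:]], axis=0) + _MARGIN_NM
    pts = [p - lo for p in pts]
    if cap_centers is not None:
        cap_centers = cap_centers - lo
    mid_xy, im_xy, om_xy = pts

    px = spec.pixel_size_nm
    n_cols = int(np.ceil((hi[0] - lo[0]) / px)) + 1
    n_rows = int(np.ceil((hi[1] - lo[1]) / px)) + 1

    sigma = spec.membrane_fwhm_nm / _FWHM_TO_SIGMA
    cols, rows = np.meshgrid(np.arange(n_cols) * px, np.arange(n_rows) * px)
    coords = np.column_stack([cols.ravel(), rows.ravel()])
    ridge = np.zeros(coords.shape[0])
    cutoff = 6.0 * sigma
    for curve in (im_xy, om_xy):
        dist, _ = cKDTree(curve).query(coords, distance_upper_bound=cutoff)
        np.nan_to_num(dist, copy=False, posinf=cutoff)
        ridge += np.exp(-0.5 * (dist / sigma) ** 2)
    ridge = ridge.reshape(n_rows, n_cols)
    if spec.polarity == "dark":
        img = 1.0 - spec.contrast * ridge
    else:
        img = spec.contrast * ridge
    if spec.blur_sigma_nm > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_nm / px, mode="reflect")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    def to_rc(p: np.ndarray) -> np.ndarray:
        return np.column_stack([p[:, 1] / px, p[:, 0] / px])

    truth = GroundTruthEnvelope(
        s_nm=s,
        im_rc=to_rc(im_xy),
        om_rc=to_rc(om_xy),
        mid_rc=to_rc(mid_xy),
        d_nm=d,
        pixel_size_nm=px,
        segment_true_means=_segment_means(s, d),
        cap_centers_rc=None if cap_centers is None else to_rc(cap_centers),
        cap_ranges_s_nm=(
            []
            if cap_mask is None
            else [
                (float(s[g[0]]), float(s[g[-1]]))
                for g in np.split(np.flatnonzero(cap_mask), np.flatnonzero(np.diff(np.flatnonzero(cap_mask)) > 1) + 1)
                if g.size
            ]
        ),
        closed=closed,
    )
    image = CalibratedImage(
        img, pixel_size_nm=px, source_id=f"synthetic(seed={spec.seed})"
    )
    return image, truth


def draw_baseline_separations(
    n: int,
    mean_nm: float,
    sd_nm: float,
    min_sep_nm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-cell baseline separations: normal draws truncated above ``min_sep_nm``.

    Exposed separately so the distributional behaviour of the cohort
    generator can be checked at large n without rendering images.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if sd_nm < 0:
        raise ParameterError("sd_nm must be non-negative")
    out = rng.normal(mean_nm, sd_nm, size=n)
    bad = out <= min_sep_nm
    while bad.any():
        out[bad] = rng.normal(mean_nm, sd_nm, size=int(bad.sum()))
        bad = out <= min_sep_nm
    return out


def generate_cohort(
    n_cells: int,
    spec_base: EnvelopeSpec,
    sep_mean_nm: float,
    sep_sd_nm: float,
    seed: int,
) -> list[tuple[CalibratedImage, GroundTruthEnvelope]]:
    """Generate a cohort of cells with between-cell separation variability.

    Per-cell baseline separations are normal draws (mean/sd as given,
    truncated to stay resolvable above the membrane FWHM and wide enough for
    the within-cell modulation); per-cell render seeds are derived
    deterministically from the cohort seed.
    """
    rng = np.random.default_rng(seed)
    min_sep = max(
        spec_base.membrane_fwhm_nm,
        2.0 * (spec_base.wrinkle_amp_nm + 3.0 * spec_base.rough_sd_nm),
    ) + 1e-9
    baselines = draw_baseline_separations(n_cells, sep_mean_nm, sep_sd_nm, min_sep, rng)
    cell_seeds = rng.integers(0, 2**31, size=n_cells)
    cohort = []
    for i in range(n_cells):
        spec = dataclasses.replace(
            spec_base, baseline_sep_nm=float(baselines[i]), seed=int(cell_seeds[i])
        )
        img, truth = generate_envelope(spec)
        img.source_id = f"cell{i:03d}(seed={spec.seed})"
        cohort.append((img, truth))
    return cohort
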