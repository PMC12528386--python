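# perimem

Measurement of the **intermembrane distance** — the center-to-center
distance between the inner membrane (IM) and outer membrane (OM) of a
Gram-negative bacterial envelope, a proxy for **periplasmic thickness** —
from calibrated 2D cryo-EM images. The package is aimed at microbiologists
and image analysts who need reproducible, per-position envelope thickness
numbers from projection images of rod-shaped cells, for example to compare
periplasmic thickness between strains of different cell width.

## What it computes

Given a grayscale image with a known pixel size (nm/px), the pipeline:

1. **enhances** membranes with a Gaussian filter (σ = 3 nm) followed by a
   circular variance filter (r = 10 nm), and thresholds the variance image
   into a membrane mask (Otsu by default);
2. **traces** the mid-envelope centerline by closing the mask into a single
   band, skeletonizing it, and smoothing the ordered skeleton into a
   subpixel path; hemispherical **poles are excluded**, either by
   user-supplied ROI boxes over cylindrical midsections or automatically by
   a local-curvature cutoff (κ > 1/500 nm⁻¹);
3. **straightens** the image along the path into an arc-length × normal-
   offset ribbon by bilinear sampling along the local normals;
4. splits the ribbon into non-overlapping **50-nm segments**, averages each
   segment's cross-profile, and locates the two most prominent membrane
   peaks; each peak center is refined to subpixel precision as the **zero
   crossing of the gray-scale gradient** (first difference of the profile,
   linearly interpolated). The per-segment distance is

   d = |x_OM − x_IM| · (nm/px),

   with QC flags (peak count, prominence, plausibility bounds 12–60 nm)
   replacing manual curation;
5. **compares groups**: box-plot summaries (median, quartiles, 1.5-IQR
   whiskers), two-tailed Student's *t* test (pooled variance by default),
   and a Pearson-correlation utility.

Because suitable raw micrographs are rarely public, the package ships a
first-class **synthetic envelope generator** (`perimem.synthmem`): two dark
Gaussian-profile ridges with analytic midlines, known separation d(s)
(sinusoidal wrinkle + smooth roughness), optional spherocylindrical poles,
blur and noise — ground truth for every stage of the pipeline.

## Worked example

Simulate two 5-cell cohorts whose true mean separations differ by 3 nm
(24.0 vs 21.0 nm, between-cell sd 1 nm), measure both, and compare:

```sh
perimem demo out/ --n-cells 5 --seed 0
```

prints

```
mean difference +2.87 nm, t=14.27, p=2.29e-25
```

and writes `out/groupA.csv`, `out/groupB.csv` (one row per 50-nm segment
with peak offsets, prominences and QC verdicts) plus `out/report.json`:

```json
"groups": [{"group_label": "wide-periplasm", "n_points": 50, "n_cells": 5,
            "mean_nm": 24.203, "median_nm": 24.068, "q1_nm": 23.574,
            "q3_nm": 24.915, "whisker_low_nm": 21.913, "whisker_high_nm": 26.140, ...}],
"t_test": {"t_stat": 14.27, "df": 95.0, "p_two_tailed": 2.29e-25,
           "method": "student_pooled"},
"mean_difference_nm": 2.87
```

The recovered difference (+2.87 nm) agrees with the constructed truth
(3.0 nm) within the sampling error of 5 cells per group; the pooled t test
treats every 50-nm segment as one observation (n = 50 + 47 here).

The same steps are available individually (`perimem simulate`, `enhance`,
`trace`, `measure`, `compare`) and as library calls:

```python
import perimem as pm

img = pm.read_image("cell.tif", pixel_size_nm=0.3266)
table = pm.measure_image(img)                 # one row per 50-nm segment
ok = pm.qc_filter(table)
print(ok["distance_nm"].describe())
```

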