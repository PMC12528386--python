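"""Shared fixtures: synthetic envelopes and an analytic annulus image.

Heavy renders are session-scoped so each image is generated once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import perimem as pm

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@pytest.fixture(scope="session")
def straight_env():
    """Noiseless straight envelope, constant separation 24 nm, 500 nm long."""
    spec = pm.EnvelopeSpec(
        length_nm=500.0, baseline_sep_nm=24.0, wrinkle_amp_nm=0.0,
        rough_sd_nm=0.0, noise_sd=0.0,
    )
    return pm.generate_envelope(spec)


@pytest.fixture(scope="session")
def wrinkled_env():
    """Noiseless wrinkled envelope: 24 +/- 2 nm sinusoidal separation."""
    spec = pm.EnvelopeSpec(
        length_nm=500.0, baseline_sep_nm=24.0, wrinkle_amp_nm=2.0,
        wrinkle_wavelength_nm=200.0, rough_sd_nm=0.0, noise_sd=0.0,
    )
    return pm.generate_envelope(spec)


@pytest.fixture(scope="session")
def spherocylinder_env():
    """Closed spherocylinder contour: caps of radius 300 nm are the only
    high-curvature regions (cap curvature 1/300 > the 1/500 cutoff)."""
    spec = pm.EnvelopeSpec(
        length_nm=300.0, baseline_sep_nm=24.0, wrinkle_amp_nm=0.0,
        rough_sd_nm=0.0, noise_sd=0.0, cap_radius_nm=300.0, pixel_size_nm=0.6,
    )
    return pm.generate_envelope(spec)


def make_annulus(
    r_inner_nm: float = 400.0,
    r_outer_nm: float = 424.0,
    pixel_size_nm: float = 0.5,
    fwhm_nm: float = 6.0,
    margin_nm: float = 45.0,
):
    """Analytic concentric-ring fixture: two dark ring ridges around a
    common center. Returns (CalibratedImage, center_rc, mid_radius_px).

    Rendered directly from the radial distance function, independently of
    the package's envelope generator.
    """
    sigma = fwhm_nm / FWHM_TO_SIGMA
    half = r_outer_nm + margin_nm
    n = int(np.ceil(2 * half / pixel_size_nm)) + 1
    c = (n - 1) / 2.0  # center in px
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    r_nm = np.hypot(yy - c, xx - c) * pixel_size_nm
    img = (
        1.0
        - np.exp(-0.5 * ((r_nm - r_inner_nm) / sigma) ** 2)
        - np.exp(-0.5 * ((r_nm - r_outer_nm) / sigma) ** 2)
    )
    cal = pm.CalibratedImage(img, pixel_size_nm, source_id="annulus")
    mid_radius_px = (r_inner_nm + r_outer_nm) / 2.0 / pixel_size_nm
    return cal, (c, c), mid_radius_px


def circle_path(center_rc, radius_px, pixel_size_nm, n_points=None):
    """Closed circular MembranePath at ~1-px arc steps."""
    if n_points is None:
        n_points = int(np.ceil(2 * np.pi * radius_px))
    th = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    pts = np.column_stack(
        [center_rc[0] + radius_px * np.sin(th), center_rc[1] + radius_px * np.cos(th)]
    )
    return pm.MembranePath(pts, pixel_size_nm, closed=True)


def two_dip_profile(offsets_nm, sep_nm, fwhm_nm=7.0, depth=1.0, background=1.0):
    """Analytic two-Gaussian-dip cross-profile centered on offset 0."""
    sigma = fwhm_nm / FWHM_TO_SIGMA
    x = np.asarray(offsets_nm, dtype=float)
    return background - depth * (
        np.exp(-0.5 * ((x + sep_nm / 2) / sigma) ** 2)
        + np.exp(-0.5 * ((x - sep_nm / 2) / sigma) ** 2)
    )
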