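"""Envelope centerline extraction, pole exclusion and image straightening.

The traced path is the *mid-envelope* centerline — the line running between
the two membranes — obtained by morphologically closing the membrane mask
(so the two ridges merge into one band), skeletonizing the band, pruning
spurs and ordering the skeleton into subpixel paths. Straightening then
resamples the intensity image along the local normal of the path at 1-px
steps, producing a rectangular arc-length x normal-offset ribbon in which
the two membranes appear as two nearly horizontal ridges symmetric about
offset zero.

Poles (hemispherical caps of rod-shaped cells) are excluded either by
explicit ROI boxes marking cylindrical midsections or, when no boxes are
given, automatically by a local-curvature cutoff: cap regions of a
spherocylinder have curvature 1/R_cell, far above that of the cylindrical
sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import AllExcludedError, NoPathError, ParameterError, SamplingBoundsError
from .imgio import CalibratedImage, RoiBox
from .enhance import MembraneMask

#: default half-width of the straightened ribbon (nm): covers separations up
#: to ~60 nm plus membrane width margins.
DEFAULT_HALF_WIDTH_NM = 40.0

#: default curvature cutoff (1/nm) for automatic pole exclusion: excludes
#: caps of radius < 500 nm, i.e. typical poles of cells up to ~1 um wide.
DEFAULT_KAPPA_MAX = 1.0 / 500.0


@dataclass
class MembranePath:
    """Ordered subpixel centerline with cumulative arc length.

    ``points`` is an (n, 2) float array of (row, col) positions; ``s_nm``
    the cumulative arc length in nm starting at 0. ``closed`` marks paths
    traced around a closed contour (the seam point is arbitrary).
    """

    points: np.ndarray
    pixel_size_nm: float
    closed: bool = False
    s_nm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ParameterError("path needs >= 2 (row, col) points")
        step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if (step <= 0).any():
            raise ParameterError("path has coincident consecutive points")
        self.points = pts
        self.s_nm = np.concatenate([[0.0], np.cumsum(step)]) * self.pixel_size_nm

    @property
    def length_nm(self) -> float:
        return float(self.s_nm[-1])


# ---------------------------------------------------------------------------
# skeleton ordering helpers

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_map(pixels: set[tuple[int, int]]) -> dict:
    return {
        p: [q for dr, dc in _NEIGHBORS if (q := (p[0] + dr, p[1] + dc)) in pixels]
        for p in pixels
    }


def _prune_spurs(pixels: set[tuple[int, int]], min_len: int) -> set[tuple[int, int]]:
    """Iteratively remove endpoint branches shorter than ``min_len`` pixels
    that terminate at a junction."""
    pixels = set(pixels)
    while True:
        nbrs = _neighbor_map(pixels)
        deg = {p: len(n) for p, n in nbrs.items()}
        junctions = {p for p, d in deg.items() if d >= 3}
        if not junctions:
            return pixels
        removed_any = False
        for end in [p for p, d in deg.items() if d == 1]:
            if end not in pixels:
                continue
            branch = [end]
            prev, cur = None, end
            while True:
                nxt = [q for q in nbrs[cur] if q != prev and q in pixels]
                if cur in junctions or not nxt or len(branch) > min_len:
                    break
                prev, cur = cur, nxt[0]
                if cur in junctions:
                    break
                branch.append(cur)
            if len(branch) <= min_len and (cur in junctions):
                pixels -= set(branch)
                removed_any = True
        if not removed_any:
            return pixels


def _order_component(comp: set[tuple[int, int]]) -> tuple[list[tuple[int, int]], bool]:
    """Order a degree-<=2 pixel component by greedy walking.

    Returns (ordered pixels, closed). Walks from an endpoint if one exists,
    else (a cycle) from an arbitrary pixel.
    """
    nbrs = _neighbor_map(comp)
    ends = [p for p, n in nbrs.items() if len(n) <= 1]
    start = min(ends) if ends else min(comp)
    order = [start]
    visited = {start}
    cur = start
    while True:
        cand = [q for q in nbrs[cur] if q not in visited]
        if not cand:
            break
        # prefer 4-connected steps so staircase diagonals don't skip pixels
        cand.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = cand[0]
        order.append(cur)
        visited.add(cur)
    closed = not ends and len(order) > 3 and order[0] in nbrs[order[-1]]
    return order, closed


def _skeleton_to_paths(skel: np.ndarray, min_len_px: int) -> list[tuple[np.ndarray, bool]]:
    pixels = set(map(tuple, np.argwhere(skel)))
    pixels = _prune_spurs(pixels, max(min_len_px // 4, 5))
    # split what remains at junction pixels, then order each simple piece
    nbrs = _neighbor_map(pixels)
    junctions = {p for p, n in nbrs.items() if len(n) >= 3}
    simple = pixels - junctions
    lbl, n_lbl = ndimage.label(
        _pixels_to_mask(simple, skel.shape), structure=np.ones((3, 3), dtype=int)
    )
    out = []
    for i in range(1, n_lbl + 1):
        comp = set(map(tuple, np.argwhere(lbl == i)))
        if len(comp) < max(min_len_px, 2):
            continue
        order, closed = _order_component(comp)
        if len(order) >= max(min_len_px, 2):
            out.append((np.asarray(order, dtype=np.float64), closed))
    return out


def _pixels_to_mask(pixels: set[tuple[int, int]], shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if pixels:
        idx = np.asarray(list(pixels))
        m[idx[:, 0], idx[:, 1]] = True
    return m


def _close_band(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological closing with a Euclidean disk via distance transforms
    (fast for the large radii needed to merge the two membrane ridges)."""
    dilated = ndimage.distance_transform_edt(~mask) <= radius_px
    eroded = ndimage.distance_transform_edt(dilated) > radius_px
    return eroded


def _extend_to_band(pts: np.ndarray, band: np.ndarray, max_steps: int) -> np.ndarray:
    """Extend an open path from both ends along the end tangents while the
    extension stays inside the (closed) membrane band.

    The skeleton of a band is the medial axis, which stops about half a
    band-width short of each end; extension recovers the full usable arc.
    """
    tail = min(40, pts.shape[0] - 1)

    def grow(anchor: np.ndarray, direction: np.ndarray) -> list[np.ndarray]:
        direction = direction / np.linalg.norm(direction)
        out = []
        for i in range(1, max_steps + 1):
            p = anchor + i * direction
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < band.shape[0] and 0 <= c < band.shape[1] and band[r, c]):
                break
            out.append(p)
        return out

    head = grow(pts[0], pts[0] - pts[tail])
    foot = grow(pts[-1], pts[-1] - pts[-1 - tail])
    parts = [np.asarray(head[::-1]), pts, np.asarray(foot)]
    return np.concatenate([p.reshape(-1, 2) for p in parts if len(p)])


def extract_path(
    mask: MembraneMask,
    pixel_size_nm: float,
    close_radius_nm: float = 20.0,
    min_path_nm: float = 50.0,
    smooth_nm: float = 3.0,
) -> list[MembranePath]:
    """Extract ordered mid-envelope centerlines from a membrane mask.

    The mask is closed with a disk of ``close_radius_nm`` (>= half the
    expected membrane separation, so the two ridges merge into one band),
    skeletonized, spur-pruned, and each remaining branch of arc length
    >= ``min_path_nm`` is returned as a subpixel path smoothed with a
    Gaussian of scale ``smooth_nm`` along the point sequence. Open paths
    are extended along their end tangents to the band boundary (the medial
    axis stops short of the band ends by about half the band width).
    """
    if not mask.mask.any():
        raise NoPathError("empty membrane mask")
    radius_px = close_radius_nm / pixel_size_nm
    band = _close_band(mask.mask, radius_px)
    skel = skeletonize(band)
    min_len_px = int(round(min_path_nm / pixel_size_nm))
    raw = _skeleton_to_paths(skel, min_len_px)
    if not raw:
        raise NoPathError("skeleton empty after pruning")
    paths = []
    sigma = smooth_nm / pixel_size_nm  # point spacing ~1 px
    max_ext = int(np.ceil(2 * radius_px))
    for pts, closed in raw:
        mode = "wrap" if closed else "nearest"
        sm = np.column_stack(
            [ndimage.gaussian_filter1d(pts[:, j], sigma, mode=mode) for j in (0, 1)]
        )
        if not closed and sm.shape[0] > 41:
            # extend with the tangent of the already-smoothed path, then
            # re-smooth so the joins carry no curvature kink
            sm = _extend_to_band(sm, band, max_ext)
            sm = np.column_stack(
                [ndimage.gaussian_filter1d(sm[:, j], sigma, mode=mode) for j in (0, 1)]
            )
        # drop accidental duplicate points created by smoothing
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(sm, axis=0), axis=1) > 1e-9]
        )
        sm = sm[keep]
        if sm.shape[0] < 2:
            continue
        paths.append(MembranePath(sm, pixel_size_nm, closed=closed))
    if not paths:
        raise NoPathError("no path survived smoothing")
    paths.sort(key=lambda p: -p.length_nm)
    return paths


# ---------------------------------------------------------------------------
# pole exclusion

def path_curvature(path: MembranePath, window_nm: float = 20.0) -> np.ndarray:
    """Local unsigned curvature (1/nm) by finite differences of the tangent
    angle over a ``window_nm`` arc window."""
    pts = path.points * path.pixel_size_nm  # to nm
    t = np.gradient(pts, axis=0)
    phi = np.unwrap(np.arctan2(t[:, 0], t[:, 1]))
    dphi_ds = np.gradient(phi, path.s_nm)
    spacing = max(np.median(np.diff(path.s_nm)), 1e-9)
    win = max(int(round(window_nm / spacing)), 1)
    return np.abs(ndimage.uniform_filter1d(dphi_ds, win, mode="nearest"))


def exclude_poles(
    path: MembranePath,
    rois: list[RoiBox] | None = None,
    kappa_max_per_nm: float = DEFAULT_KAPPA_MAX,
    min_fragment_nm: float = 50.0,
    curvature_window_nm: float = 20.0,
) -> list[MembranePath]:
    """Clip a path to cylindrical midsections.

    With ROI boxes, the path is clipped to the portions inside any box
    (boxes take precedence, mirroring manually drawn midsection boxes).
    Without boxes, points whose local curvature exceeds
    ``kappa_max_per_nm`` are removed and the path split at the removals.
    Fragments shorter than ``min_fragment_nm`` (one measurement segment)
    are dropped; if nothing survives an :class:`AllExcludedError` is raised.
    """
    if rois:
        keep = np.array(
            [any(b.contains(r, c) for b in rois) for r, c in path.points]
        )
    else:
        kappa = path_curvature(path, curvature_window_nm)
        keep = kappa <= kappa_max_per_nm
        if path.closed and keep.all():
            # closed contour with no high-curvature region: seam tangents are
            # unreliable, but the whole loop is usable as one open run
            keep[0] = False
    fragments: list[MembranePath] = []
    idx = np.flatnonzero(keep)
    if idx.size:
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if run.size < 2:
                continue
            frag = MembranePath(
                path.points[run], path.pixel_size_nm, closed=False
            )
            if frag.length_nm >= min_fragment_nm:
                fragments.append(frag)
    if not fragments:
        raise AllExcludedError(
            "pole exclusion removed the entire path "
            f"(kept {int(keep.sum())}/{keep.size} points)"
        )
    return fragments


# ---------------------------------------------------------------------------
# straightening

@dataclass
class StraightRibbon:
    """Straightened image: rows = signed normal offset, cols = arc length.

    ``offset_zero_row`` is the row corresponding to offset 0 (the path);
    both axes are sampled at 1-px steps so ``offset_nm_per_row`` and
    ``arc_nm_per_col`` equal the parent pixel size. ``path_points`` holds
    the resampled (row, col) path position of every column.
    """

    values: np.ndarray
    offset_nm_per_row: float
    arc_nm_per_col: float
    offset_zero_row: int
    path_points: np.ndarray
    parent_id: str = ""

    @property
    def offsets_nm(self) -> np.ndarray:
        return (
            np.arange(self.values.shape[0]) - self.offset_zero_row
        ) * self.offset_nm_per_row

    @property
    def arc_nm(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.arc_nm_per_col

    @property
    def length_nm(self) -> float:
        return self.values.shape[1] * self.arc_nm_per_col


def _resample_1px(path: MembranePath) -> np.ndarray:
    """Resample the path at 1-px arc-length steps."""
    s_px = path.s_nm / path.pixel_size_nm
    targets = np.arange(0.0, s_px[-1] + 1e-9, 1.0)
    rows = np.interp(targets, s_px, path.points[:, 0])
    cols = np.interp(targets, s_px, path.points[:, 1])
    return np.column_stack([rows, cols])


def straighten(
    img: CalibratedImage,
    path: MembranePath,
    half_width_nm: float = DEFAULT_HALF_WIDTH_NM,
    tangent_smooth_nm: float = 10.0,
) -> StraightRibbon:
    """Resample the image along the path's local normals into a ribbon.

    At every 1-px arc step, intensities are sampled by bilinear
    interpolation at 1-px offsets in [-half_width, +half_width] along the
    unit normal. Normals come from a Gaussian-smoothed tangent
    (``tangent_smooth_nm`` window) so mask-tracing jitter does not tilt the
    sampling direction. Raises :class:`SamplingBoundsError` if any sample
    would fall outside the image.
    """
    if path.pixel_size_nm != img.pixel_size_nm:
        raise ParameterError("path and image calibrations differ")
    pts = _resample_1px(path)
    sigma = tangent_smooth_nm / img.pixel_size_nm
    sm = np.column_stack(
        [ndimage.gaussian_filter1d(pts[:, j], sigma, mode="nearest") for j in (0, 1)]
    )
    t = np.gradient(sm, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    t /= norms
    normal = np.column_stack([-t[:, 1], t[:, 0]])  # +90 deg rotation

    k = int(round(half_width_nm / img.pixel_size_nm))
    offsets = np.arange(-k, k + 1, dtype=np.float64)
    rows = pts[None, :, 0] + offsets[:, None] * normal[None, :, 0].squeeze(0)
    cols = pts[None, :, 1] + offsets[:, None] * normal[None, :, 1].squeeze(0)
    nr, nc = img.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > nr - 1 or cols.max() > nc - 1:
        raise SamplingBoundsError(
            "straightening samples outside the image; reduce half_width_nm "
            "or enlarge the image margin"
        )
    values = ndimage.map_coordinates(img.pixels, [rows, cols], order=1)
    return StraightRibbon(
        values=values,
        offset_nm_per_row=img.pixel_size_nm,
        arc_nm_per_col=img.pixel_size_nm,
        offset_zero_row=k,
        path_points=pts,
        parent_id=img.source_id,
    )
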