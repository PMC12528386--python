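"""Calibrated image, ROI and measurement-table I/O.

All coordinate and calibration conventions live here:

* rasters are indexed ``(row, col)``, 0-based, pixel centers at integer
  coordinates;
* ROI boxes are half-open ``[row0, row0+height) x [col0, col0+width)``;
* every physical quantity in nm equals the pixel quantity times
  ``pixel_size_nm`` (isotropic) — there is no second calibration path.

Images are written as single-page grayscale TIFFs with the pixel size
embedded in the image description as JSON, so a write/read round trip
preserves both data and calibration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationError, ImageFormatError, RoiBoundsError

#: Pixel size of the acquisition the pipeline defaults emulate (nm/px).
DEFAULT_PIXEL_SIZE_NM = 0.3266

MIN_IMAGE_DIM = 16


@dataclass
class CalibratedImage:
    """A 2D intensity grid with an isotropic nm-per-pixel calibration.

    Parameters
    ----------
    pixels
        2D float array (rows x cols). Integer input is promoted to float64
        with values unchanged.
    pixel_size_nm
        Physical edge length of one pixel in nanometres; must be positive.
    source_id
        Free-text provenance (file name, generator spec, ...).
    """

    pixels: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError(f"expected a 2D grid, got ndim={px.ndim}")
        if px.shape[0] < MIN_IMAGE_DIM or px.shape[1] < MIN_IMAGE_DIM:
            raise ImageFormatError(
                f"image {px.shape} smaller than {MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}"
            )
        px = px.astype(np.float64, copy=False)
        if not np.all(np.isfinite(px)):
            raise ImageFormatError("image contains non-finite intensities")
        if not (self.pixel_size_nm > 0 and math.isfinite(self.pixel_size_nm)):
            raise CalibrationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def nm(self, px: float) -> float:
        """Convert a pixel quantity to nm."""
        return px * self.pixel_size_nm

    def px(self, nm: float) -> float:
        """Convert an nm quantity to pixels."""
        return nm / self.pixel_size_nm


@dataclass(frozen=True)
class RoiBox:
    """Half-open rectangular region ``[row0, row0+height) x [col0, col0+width)``."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise RoiBoundsError(f"ROI must have positive extent, got {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise RoiBoundsError(f"ROI corner must be non-negative, got {self}")

    @property
    def area(self) -> int:
        return self.height * self.width

    def fits(self, shape: tuple[int, int]) -> bool:
        return self.row0 + self.height <= shape[0] and self.col0 + self.width <= shape[1]

    def contains(self, row: float, col: float) -> bool:
        """Whether a (possibly subpixel) point falls inside the box."""
        return (
            self.row0 <= row < self.row0 + self.height
            and self.col0 <= col < self.col0 + self.width
        )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width] = True
        return m


def read_image(path: str | Path, pixel_size_nm: float | None = None) -> CalibratedImage:
    """Read a 2D grayscale TIFF as a :class:`CalibratedImage`.

    The pixel size is taken from the explicit ``pixel_size_nm`` argument if
    given; otherwise from a JSON image description written by
    :func:`write_image`; otherwise a :class:`CalibrationError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_size = None
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                meta_size = float(meta["pixel_size_nm"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                meta_size = None
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ImageFormatError(
            f"{path.name}: expected a single 2D grayscale plane, got shape {data.shape}"
        )
    size = pixel_size_nm if pixel_size_nm is not None else meta_size
    if size is None:
        raise CalibrationError(
            f"{path.name}: no pixel size in metadata and none given explicitly"
        )
    return CalibratedImage(data, pixel_size_nm=size, source_id=path.name)


def write_image(img: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image as a float TIFF with embedded calibration."""
    desc = json.dumps({"pixel_size_nm": img.pixel_size_nm})
    tifffile.imwrite(Path(path), img.pixels.astype(np.float64), description=desc)


def read_rois(path: str | Path, image: CalibratedImage) -> list[RoiBox]:
    """Read ROI boxes from delimited text with columns row0,col0,height,width.

    Lines starting with ``#`` and an optional non-numeric header line are
    skipped. Every box is validated against the image; an out-of-bounds box
    raises :class:`RoiBoundsError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    boxes: list[RoiBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        try:
            vals = [int(p) for p in parts]
        except ValueError:
            if lineno == 1 or (lineno == 2 and not boxes):
                continue  # header
            raise RoiBoundsError(f"{path.name}:{lineno}: non-integer ROI record {line!r}")
        if len(vals) != 4:
            raise RoiBoundsError(
                f"{path.name}:{lineno}: expected 4 fields (row0,col0,height,width), got {len(vals)}"
            )
        box = RoiBox(*vals)
        if not box.fits(image.shape):
            raise RoiBoundsError(
                f"{path.name}:{lineno}: ROI {vals} exceeds image of shape {image.shape}"
            )
        boxes.append(box)
    return boxes


# ---------------------------------------------------------------------------
# Measurement tables

TABLE_COLUMNS = [
    "source_id",
    "group_label",
    "cell_id",
    "segment_index",
    "arc_start_nm",
    "arc_end_nm",
    "distance_nm",
    "peak_im_nm",
    "peak_om_nm",
    "prominence_im",
    "prominence_om",
    "qc_pass",
    "qc_reason",
]

_STR_COLS = ["source_id", "group_label", "cell_id", "qc_reason"]
_FLOAT_COLS = [
    "arc_start_nm",
    "arc_end_nm",
    "distance_nm",
    "peak_im_nm",
    "peak_om_nm",
    "prominence_im",
    "prominence_om",
]


def empty_table() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in TABLE_COLUMNS})
    return _coerce_table(df)


def _coerce_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df[TABLE_COLUMNS].copy()
    for c in _STR_COLS:
        df[c] = df[c].astype(str)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(np.float64)
    df["segment_index"] = df["segment_index"].astype(np.int64)
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return df.reset_index(drop=True)


def validate_table(df: pd.DataFrame) -> None:
    """Check the measurement-table invariants, raising ValueError on failure."""
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    if len(df) == 0:
        return
    dup = df.duplicated(subset=["source_id", "cell_id", "segment_index"])
    if dup.any():
        raise ValueError("segment_index not unique within (source_id, cell_id)")
    ok = df[df["qc_pass"]]
    if len(ok) and not (ok["distance_nm"] > 0).all():
        raise ValueError("non-positive distance on a qc_pass row")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV.

    Floats are serialized with the shortest representation that round-trips
    exactly, so ``read_table(write_table(t)) == t`` bit for bit.
    """
    validate_table(df)
    _coerce_table(df).to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        Path(path),
        dtype={c: str for c in _STR_COLS},
        keep_default_na=False,
    )
    if len(df) == 0 and "qc_pass" not in df.columns:
        raise ValueError(f"{path}: not a measurement table")
    if len(df):
        df["qc_pass"] = df["qc_pass"].map({"True": True, "False": False, True: True, False: False})
    return _coerce_table(df)
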