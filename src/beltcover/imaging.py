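"""Plate-photograph processing: grayscale conversion, global thresholding and
coverage quantification.

The measurement chain mirrors the standard binary-image area-fraction method
used in plan-view livestock-manure monitoring: an 8-bit colour photograph of a
white polypropylene plate is converted to grayscale, thresholded at a global
intensity ``T`` (default 200) so that manure pixels become 0 (black) and the
plate background becomes 255 (white), and the coverage proportion ``gamma`` is
the black-pixel fraction in percent.  The projected manure area follows from
the known physical plate area.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PlateSpec",
    "CoverageSample",
    "DEFAULT_THRESHOLD",
    "to_grayscale",
    "binarize",
    "coverage_proportion",
    "projected_area",
    "process_photo",
    "write_series",
    "read_series",
]

#: Global grayscale threshold separating manure (dark) from plate (bright).
DEFAULT_THRESHOLD: int = 200

# ITU-R BT.601 luma weights; the common default of image toolchains.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

SERIES_COLUMNS = ["hour", "gamma_pct", "area_m2", "mass_g"]


@dataclass(frozen=True)
class PlateSpec:
    """Physical geometry of a manure-collection plate.

    The default dimensions are those of a polypropylene plate spanning one
    cage on the manure belt: 0.86 m long and 0.68 m wide (0.5848 m^2).
    """

    length_m: float = 0.86
    width_m: float = 0.68

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.width_m <= 0:
            raise ValueError("plate dimensions must be positive")

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m


@dataclass
class CoverageSample:
    """One hourly coverage measurement from a single plate photograph.

    ``hour`` counts from the most recent manure removal (1-based; the sample
    is taken at the end of the hour).  ``gamma_pct`` is the coverage
    proportion in percent, ``area_m2`` the projected manure area and
    ``mass_g`` the cumulative manure mass on the plate if weighed.
    """

    hour: int
    gamma_pct: float
    area_m2: float
    mass_g: float | None = None
    threshold_used: int = field(default=DEFAULT_THRESHOLD)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_pct <= 100.0:
            raise ValueError(f"gamma_pct {self.gamma_pct} outside [0, 100]")
        if self.mass_g is not None and self.mass_g < 0:
            raise ValueError("mass_g must be non-negative")


def _as_uint8(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got dtype {arr.dtype}")
    return arr


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to grayscale by BT.601 luminance.

    Per-pixel ``0.299 R + 0.587 G + 0.114 B`` rounded to the nearest integer;
    a single-channel 8-bit input is passed through unchanged.
    """
    arr = _as_uint8(image)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    rgb = arr[..., :3].astype(np.float64)
    gray = np.rint(rgb @ _LUMA_WEIGHTS)
    return np.clip(gray, 0, 255).astype(np.uint8)


def binarize(gray: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a grayscale image to a {0, 255} binary image.

    Intensities below ``threshold`` map to 0 (object/manure); intensities at
    or above it map to 255 (background).  A pixel exactly at the threshold is
    background: only values *smaller* than T are object.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    arr = _as_uint8(gray)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {arr.shape}")
    return np.where(arr < threshold, 0, 255).astype(np.uint8)


def coverage_proportion(binary: np.ndarray) -> float:
    """Coverage proportion gamma in percent: black pixels / total pixels x 100."""
    arr = np.asarray(binary)
    if arr.size == 0:
        raise ValueError("empty image")
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, 255))):
        raise ValueError("binary image must contain only values 0 and 255")
    return float(np.count_nonzero(arr == 0) / arr.size * 100.0)


def projected_area(gamma_pct: float, plate: PlateSpec) -> float:
    """Projected manure area in m^2 from coverage percent and plate geometry."""
    if not 0.0 <= gamma_pct <= 100.0:
        raise ValueError(f"gamma_pct {gamma_pct} outside [0, 100]")
    return gamma_pct / 100.0 * plate.area_m2


def process_photo(
    path: str | os.PathLike,
    plate: PlateSpec,
    threshold: int = DEFAULT_THRESHOLD,
    hour: int = 1,
) -> CoverageSample:
    """Measure one plate photograph: read, grayscale, threshold, count.

    The photograph is assumed to be cropped to the plate extent (the field
    protocol uses a fixed camera over a pre-marked area), so the pixel
    fraction maps directly to the physical plate area.
    """
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB") if img.mode not in ("L", "RGB") else img)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    gray = to_grayscale(arr)
    binary = binarize(gray, threshold)
    gamma = coverage_proportion(binary)
    return CoverageSample(
        hour=hour,
        gamma_pct=gamma,
        area_m2=projected_area(gamma, plate),
        threshold_used=threshold,
    )


def write_binary_mask(binary: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0, 255} binary mask as an 8-bit PNG."""
    arr = np.asarray(binary)
    if not np.all(np.isin(np.unique(arr), (0, 255))):
        raise ValueError("binary mask must contain only values 0 and 255")
    Image.fromarray(arr.astype(np.uint8)).save(path)


def write_series(samples: list[CoverageSample] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an hourly coverage series as CSV (hour,gamma_pct,area_m2,mass_g)."""
    if isinstance(samples, pd.DataFrame):
        df = samples.loc[:, SERIES_COLUMNS]
    else:
        df = pd.DataFrame(
            [(s.hour, s.gamma_pct, s.area_m2, s.mass_g) for s in samples],
            columns=SERIES_COLUMNS,
        )
    df.to_csv(path, index=False)


def read_series(path: str | os.PathLike) -> pd.DataFrame:
    """Read an hourly coverage series CSV, validating the expected header."""
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed series CSV {path!r}: missing columns {missing}; "
            f"expected header {','.join(SERIES_COLUMNS)}"
        )
    if "mass_g" not in df.columns:
        df["mass_g"] = np.nan
    hours = df["hour"].to_numpy()
    gaps = sorted(set(range(int(hours.min()), int(hours.max()) + 1)) - set(hours.astype(int)))
    if gaps:
        warnings.warn(f"series {path!r} has missing hours: {gaps}", stacklevel=2)
    return df.sort_values("hour", ignore_index=True)
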