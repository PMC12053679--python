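"""Reading and writing gel images, segmentation masks and measurement tables.

Conventions shared by every module in the package:

* coordinates are ``(row, col)``, 0-based, origin at the top-left corner;
  the row index increases in the direction of band migration;
* pixel intensities are kept raw — loading never rescales, filters or
  otherwise post-processes the data;
* class masks are binary: 0 = background, 1 = band.  Instance masks carry
  one positive integer label per band with 0 reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

# ITU-R BT.601 luminance weights, the conventional RGB collapse.
_LUMA = np.array([0.299, 0.587, 0.114])

MEASUREMENT_COLUMNS = [
    "band_id",
    "lane_id",
    "centroid_row",
    "centroid_col",
    "raw_volume",
    "corrected_volume",
    "method",
]


class GelImageError(ValueError):
    """Raised for unreadable files or unsupported sample types."""


@dataclass
class GelImage:
    """A single-channel gel image with its native bit depth.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Non-negative intensities, never rescaled from the source file.
    bit_depth : {8, 16}
        Sample depth of the source data.
    source_path : str, optional
        Where the image was loaded from, if anywhere.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise GelImageError(f"gel image must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise GelImageError("gel image must have at least one row and one column")
        if self.bit_depth not in (8, 16):
            raise GelImageError(f"unsupported bit depth {self.bit_depth}; expected 8 or 16")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > self.max_value):
            raise GelImageError(f"pixel values outside [0, {self.max_value}]")

    @property
    def max_value(self) -> int:
        """Maximum representable intensity: 255 (8-bit) or 65535 (16-bit)."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentationMask:
    """Binary per-pixel band/background classes paired with one image."""

    classes: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise GelImageError(f"mask must be 2-D, got shape {self.classes.shape}")
        vals = np.unique(self.classes)
        if not np.isin(vals, [0, 1]).all():
            raise GelImageError(f"mask classes must be 0/1, found {vals}")
        self.classes = self.classes.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


def _collapse_rgb(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to luminance grayscale, preserving dtype scale."""
    rgb = arr[..., :3].astype(np.float64)
    gray = rgb @ _LUMA
    return np.rint(gray).astype(arr.dtype)


def read_gel_image(path: str | Path) -> GelImage:
    """Load a PNG or TIFF gel image, inferring bit depth from the sample type.

    RGB input is collapsed to luminance grayscale; intensities are otherwise
    untouched (no normalisation, no filtering).

    Raises
    ------
    GelImageError
        If the file cannot be read or has an unsupported sample type
        (e.g. floating-point TIFF).
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise GelImageError(f"could not read image {path}: {exc}") from exc

    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise GelImageError(
            f"unsupported sample type {arr.dtype} in {path}; expected uint8 or uint16"
        )
    if arr.ndim == 3:
        arr = _collapse_rgb(arr)
    elif arr.ndim != 2:
        raise GelImageError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return GelImage(pixels=arr, bit_depth=depth, source_path=str(path))


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> SegmentationMask:
    """Load a single-channel label image as a binary class mask.

    Any nonzero label collapses to class 1 (band); instance identity from
    label maps is therefore not preserved here — use :func:`read_label_map`
    to keep instance labels.

    Raises
    ------
    GelImageError
        On shape mismatch against ``shape`` or a multi-channel file.
    """
    labels = read_label_map(path)
    if shape is not None and tuple(labels.shape) != tuple(shape):
        raise GelImageError(f"mask shape {labels.shape} does not match expected {tuple(shape)}")
    return SegmentationMask(classes=(labels > 0).astype(np.uint8))


def read_label_map(path: str | Path) -> np.ndarray:
    """Load a single-channel instance label image (0 = background)."""
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise GelImageError(f"could not read label image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise GelImageError(f"label image must be single-channel, got shape {arr.shape}")
    return arr


def write_image(image: GelImage, path: str | Path) -> None:
    """Write a GelImage as PNG or TIFF at its native bit depth."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = image.pixels.astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an instance label map as 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > 65535:
        raise GelImageError("more than 65535 instances cannot be stored as 16-bit labels")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def write_measurements(records: list[dict], path: str | Path) -> None:
    """Write band measurements to CSV with a stable column order.

    Rows are sorted by ``(lane_id, centroid_row)``; bands without a lane sort
    last.  ``records`` entries are mappings with at least ``band_id``,
    ``raw_volume``, ``corrected_volume`` and ``method`` keys.
    """
    df = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)
    if len(df):
        lane_key = df["lane_id"].to_numpy(dtype=float, na_value=np.inf)
        df = df.iloc[np.lexsort((df["centroid_row"].to_numpy(), lane_key))]
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write measurements to {path}: {exc}") from exc


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path)


def load_mass_table(path: str | Path) -> pd.DataFrame:
    """Read a ladder mass table CSV (band index -> mass in ng)."""
    df = pd.read_csv(path)
    if "mass" not in df.columns:
        raise GelImageError(f"mass table {path} lacks a 'mass' column")
    return df
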