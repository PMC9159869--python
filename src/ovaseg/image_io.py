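"""Grayscale image and label-map I/O.

All algorithms in this package operate on a working gray range of
[0, 255] stored as floating point, with (row, col) 0-based coordinates
and row 0 at the top.  Loading converts whatever the file holds (8-bit,
16-bit, RGB) onto that range; label maps round-trip losslessly through
16-bit PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

GRAY_MAX = 255.0

# Rec. 601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of gray intensities in the working range [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("invalid intensity: non-finite pixel values")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LabelMap:
    """Integer partition of a pixel grid into regions labelled 1..K.

    Label 0 is reserved for "unassigned" and never appears in a final
    segmentation output.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("LabelMap requires a 2-D array")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("LabelMap requires integer labels")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", lab.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_regions(self) -> int:
        return len(np.unique(self.labels[self.labels > 0]))

    def compacted(self) -> "LabelMap":
        """Relabel to contiguous 1..K preserving label order."""
        uniq = np.unique(self.labels)
        uniq = uniq[uniq > 0]
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int64)
        lut[uniq] = np.arange(1, len(uniq) + 1)
        return LabelMap(lut[self.labels])


def load_grayscale(path: str | Path) -> GrayImage:
    """Read a PNG or TIFF image as a GrayImage on [0, 255].

    Multi-channel inputs are reduced to luminance (Rec. 601 weights);
    integer bit depths are rescaled linearly so the dtype's full range
    maps onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError(f"unsupported image format: {path.suffix}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float64) * (GRAY_MAX / info.max)
    else:
        arr = arr.astype(np.float64)
    return GrayImage(np.clip(arr, 0.0, GRAY_MAX))


def save_label_map(path: str | Path, labels: LabelMap) -> None:
    """Write a LabelMap as a lossless 16-bit PNG whose pixel values are the labels."""
    path = Path(path)
    lab = labels.labels
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("cannot write: more than 65535 labels")
    try:
        iio.imwrite(path, lab.astype(np.uint16), extension=".png")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot write: {path}") from exc


def save_grayscale(path: str | Path, img: GrayImage) -> None:
    """Write a GrayImage as an 8-bit PNG (grays rounded to the 8-bit grid)."""
    arr = np.clip(np.rint(img.pixels), 0, GRAY_MAX).astype(np.uint8)
    try:
        iio.imwrite(Path(path), arr, extension=".png")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot write: {path}") from exc


def load_label_map(path: str | Path) -> LabelMap:
    """Read a label map written by :func:`save_label_map`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return LabelMap(iio.imread(path).astype(np.int64))


def normalize(img: GrayImage) -> GrayImage:
    """Min-max stretch intensities onto [0, 255]; constant images map to 0."""
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return GrayImage(np.zeros_like(px))
    if lo >= 0.0 and hi <= GRAY_MAX and lo == 0.0 and hi == GRAY_MAX:
        return GrayImage(px.copy())
    return GrayImage((px - lo) * (GRAY_MAX / (hi - lo)))
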