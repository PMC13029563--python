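"""Densitometry of dried blood spot images.

A scanned DBS card is reduced to two numbers per spot: the mean gray
value (MGV, 0 = black to 255 = white) of the pixels inside the spot,
which darkens with hematocrit, and the spot's surface area, which
shrinks with hematocrit because viscous high-HCT blood spreads less.
This module segments a single spot from a raster image and measures
both quantities; calibration against spots of known HCT is handled in
:mod:`dbsbias.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "SpotImage",
    "SpotMeasurement",
    "NoSpotError",
    "segment_spot",
    "measure_spot",
    "load_image",
    "save_image",
]

#: ITU-R BT.601 luma weights used to collapse RGB scans to gray.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Default fixed segmentation threshold (gray levels). Background is
#: ~255 and the darkest calibrated spot interior is ~94, so 200 leaves
#: a wide margin on both sides.
DEFAULT_THRESHOLD = 200.0


class NoSpotError(ValueError):
    """Raised when segmentation finds no foreground pixel."""


@dataclass(frozen=True)
class SpotImage:
    """A grayscale raster of a single spot.

    Parameters
    ----------
    pixels
        2-D array of gray levels in [0, 255]. Stored as float so that
        synthetic noise-free spots keep their exact model gray value;
        8-bit files are promoted on load.
    pixel_size
        Physical edge length of one pixel in mm.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError("spot image must be a 2-D grid of at least 8x8 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SpotMeasurement:
    """Densitometric summary of one segmented spot."""

    mgv: float
    area_mm2: float
    pixel_count: int
    mask_centroid: tuple[float, float]
    flags: tuple[str, ...] = field(default=())


def load_image(path: str | Path, pixel_size: float | None = None) -> SpotImage:
    """Read a PNG/TIFF spot scan as a :class:`SpotImage`.

    RGB inputs are converted to gray with BT.601 luma weights. If
    ``pixel_size`` is not given, a sidecar YAML (``<path>.yaml`` with key
    ``pixel_size_mm``) is consulted.
    """
    path = Path(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if pixel_size is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if not sidecar.exists():
            raise ValueError(
                f"pixel_size not given and no sidecar {sidecar.name} found"
            )
        pixel_size = float(yaml.safe_load(sidecar.read_text())["pixel_size_mm"])
    return SpotImage(pixels=arr.astype(float), pixel_size=pixel_size)


def save_image(image: SpotImage, path: str | Path) -> Path:
    """Write an 8-bit grayscale PNG plus a pixel-size sidecar YAML.

    Gray levels are rounded to integers; in-memory analysis of synthetic
    spots should use the float array directly when exactness matters.
    """
    path = Path(path)
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump({"pixel_size_mm": float(image.pixel_size)}))
    return path


def segment_spot(
    image: SpotImage,
    threshold_policy: str = "fixed",
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Segment the spot as the largest dark connected component.

    A pixel is foreground iff its (center) gray value is strictly below
    the threshold; components use 4-connectivity and the largest one is
    returned as a boolean mask. This mirrors a wand-tool selection of a
    dark spot on a white card.

    Parameters
    ----------
    threshold_policy
        ``"fixed"`` uses ``threshold`` (default 200); ``"otsu"`` derives
        the threshold from the image histogram, for degraded scans.
    """
    if threshold_policy == "otsu":
        threshold = float(threshold_otsu(image.pixels))
    elif threshold_policy != "fixed":
        raise ValueError(f"unknown threshold policy: {threshold_policy!r}")

    fg = image.pixels < threshold
    if not fg.any():
        raise NoSpotError("no spot detected: no pixel below threshold")
    labels = measure.label(fg, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    return labels == int(np.argmax(counts))


def measure_spot(image: SpotImage, mask: np.ndarray) -> SpotMeasurement:
    """Mean gray value and physical area of the masked spot.

    MGV is the arithmetic mean of the gray values under the mask; area is
    the pixel count times the squared pixel size.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    rows, cols = np.nonzero(mask)
    return SpotMeasurement(
        mgv=float(image.pixels[mask].mean()),
        area_mm2=n * image.pixel_size**2,
        pixel_count=n,
        mask_centroid=(float(rows.mean()), float(cols.mean())),
    )
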