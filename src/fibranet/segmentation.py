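"""Micrograph binarisation and manual-mask ingestion.

Two automatic thresholding families (global Otsu, adaptive mean) plus a
fixed threshold are provided; externally produced masks are loaded with a
``manual`` provenance tag so downstream reports can record which
segmentation produced each descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_local, threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import ConfigurationError, FormatError

__all__ = ["Micrograph", "BinaryMask", "binarize", "load_mask", "save_mask"]

#: default speck-noise removal threshold (μm²)
DEFAULT_MIN_OBJECT_AREA_UM2 = 0.05


@dataclass
class Micrograph:
    """A 2-D intensity image with physical pixel size.

    Parameters
    ----------
    grid:
        2-D array of intensities (8- or 16-bit, or float).
    pixel_size:
        Physical size of one pixel in μm.
    source:
        Free-form identifier of where the image came from.
    """

    grid: np.ndarray
    pixel_size: float
    source: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ConfigurationError("micrograph grid must be non-empty and 2-D")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be positive (μm/px)")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def area_um2(self) -> float:
        """Physical frame area in μm²."""
        return self.grid.size * self.pixel_size**2

    @classmethod
    def read(cls, path, pixel_size: float) -> "Micrograph":
        grid = iio.imread(path)
        if grid.ndim == 3:  # collapse trivial channel axes only
            if grid.shape[2] == 1:
                grid = grid[:, :, 0]
            else:
                raise FormatError(
                    f"{path}: expected a single-channel image, got shape {grid.shape}"
                )
        return cls(grid=grid, pixel_size=pixel_size, source=str(path))

    def write(self, path) -> None:
        iio.imwrite(path, np.asarray(self.grid, dtype=np.uint8))


@dataclass
class BinaryMask:
    """Boolean fiber/background mask (``True`` = fiber)."""

    grid: np.ndarray
    pixel_size: float
    provenance: str = "automatic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ConfigurationError("mask grid must be non-empty and 2-D")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be positive (μm/px)")

    @property
    def shape(self):
        return self.grid.shape

    @property
    def area_um2(self) -> float:
        return self.grid.size * self.pixel_size**2

    @property
    def fiber_area_fraction(self) -> float:
        return float(self.grid.mean())


def binarize(
    m: Micrograph,
    method: str = "global-otsu",
    *,
    threshold: float | None = None,
    block_size_um: float = 2.0,
    offset: float = 0.0,
    min_object_area_um2: float = DEFAULT_MIN_OBJECT_AREA_UM2,
) -> BinaryMask:
    """Threshold a micrograph into a fiber/background mask.

    ``method`` is one of ``global-otsu``, ``adaptive-mean`` or ``fixed``
    (the latter requires ``threshold``).  Connected foreground components
    smaller than ``min_object_area_um2`` are removed afterwards; pass 0 to
    keep everything.  A constant-intensity image cannot be thresholded by
    Otsu and yields an all-background mask with a warning.
    """
    grid = np.asarray(m.grid)
    if method == "fixed":
        if threshold is None:
            raise ConfigurationError("fixed method requires a threshold")
        lo, hi = grid.min(), grid.max()
        if not (lo <= threshold <= hi) and not (lo == hi):
            raise ConfigurationError(
                f"fixed threshold {threshold} outside intensity range [{lo}, {hi}]"
            )
        fg = grid >= threshold
    elif method == "global-otsu":
        if grid.min() == grid.max():
            warnings.warn(
                "constant-intensity image: Otsu is degenerate, returning all background",
                stacklevel=2,
            )
            fg = np.zeros_like(grid, dtype=bool)
        else:
            fg = grid > threshold_otsu(grid)
    elif method == "adaptive-mean":
        block = int(round(block_size_um / m.pixel_size))
        block = max(block | 1, 3)  # odd, >= 3
        fg = grid > threshold_local(grid, block_size=block, method="mean", offset=offset)
    else:
        raise ConfigurationError(
            f"unknown method {method!r}; expected global-otsu, adaptive-mean or fixed"
        )

    if min_object_area_um2 > 0:
        min_px = int(np.ceil(min_object_area_um2 / m.pixel_size**2))
        if min_px > 1:
            # removes components strictly smaller than min_px pixels
            fg = remove_small_objects(fg, max_size=min_px - 1)

    return BinaryMask(
        grid=fg,
        pixel_size=m.pixel_size,
        provenance="automatic",
        meta={"method": method, "min_object_area_um2": min_object_area_um2},
    )


def load_mask(path, pixel_size: float, expected_shape=None) -> BinaryMask:
    """Read an externally produced (manual) mask; nonzero pixels are fiber."""
    grid = iio.imread(path)
    if grid.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel mask image, got shape {grid.shape}"
        )
    if expected_shape is not None and tuple(grid.shape) != tuple(expected_shape):
        raise FormatError(
            f"{path}: mask shape {grid.shape} does not match expected {tuple(expected_shape)}"
        )
    return BinaryMask(grid=grid != 0, pixel_size=pixel_size, provenance="manual")


def save_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit PNG/TIFF with values {0, 255}."""
    iio.imwrite(path, (mask.grid.astype(np.uint8) * 255))
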