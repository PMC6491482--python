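"""Core in-memory containers shared by every pipeline stage.

Intensity convention: the canonical working scale is 0–255 (256-class
histograms are the basis of the adaptive threshold), with a normalized
[0, 1] view used only by the cut-off intensity rule. The conversion
factor between the two views is exactly 255.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrayImage",
    "ImageStack",
    "BinaryMask",
    "LabelMask",
]


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 2D image on the canonical 0–255 intensity scale.

    ``values8`` is float so that linearly rescaled >8-bit data keeps
    sub-integer precision; histogramming rounds to the nearest class.
    """

    values8: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values8, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("GrayImage expects a 2D array")
        if arr.size == 0:
            raise ValueError("GrayImage is empty")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("GrayImage intensities must lie in [0, 255]")
        object.__setattr__(self, "values8", arr)

    @property
    def normalized(self) -> np.ndarray:
        """The [0, 1] view of the image (values8 / 255)."""
        return self.values8 / 255.0

    @property
    def height(self) -> int:
        return self.values8.shape[0]

    @property
    def width(self) -> int:
        return self.values8.shape[1]


@dataclass
class ImageStack:
    """An ordered z-stack of multi-channel slices plus voxel metadata.

    ``data`` has shape (n_slices, height, width, n_channels) on the 0–255
    scale. ``channel_map`` maps a biological role ("membrane" for the
    F-actin/phalloidin stain, "nuclei" for DAPI) to a channel index.
    Slice 0 is the first acquired frame, i.e. the top of the spheroid
    dome away from the culture surface.
    """

    data: np.ndarray
    channel_map: dict[str, int]
    pixel_size_xy: float
    voxel_depth: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError("stack data must be (n_slices, H, W, C)")
        if self.pixel_size_xy <= 0 or self.voxel_depth <= 0:
            raise ValueError("voxel dimensions must be positive")
        n_channels = arr.shape[3]
        for role, idx in self.channel_map.items():
            if not 0 <= idx < n_channels:
                raise ValueError(
                    f"channel_map[{role!r}] = {idx} outside 0..{n_channels - 1}"
                )
        self.data = arr

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]


@dataclass
class BinaryMask:
    """Per-slice boolean segmentation mask carrying the pixel size.

    Areas convert to µm² as ``pixel_count * pixel_size_xy**2``.
    """

    values: np.ndarray
    pixel_size_xy: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")

    def area_um2(self) -> float:
        """Total foreground area in µm²."""
        return float(self.values.sum()) * self.pixel_size_xy**2

    def is_empty(self) -> bool:
        return not bool(self.values.any())


@dataclass
class LabelMask:
    """Per-slice integer label image; 0 is background."""

    values: np.ndarray
    pixel_size_xy: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        self.values = arr

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.values[self.values > 0])))

    def binary(self) -> BinaryMask:
        """Foreground (any label) as a BinaryMask."""
        return BinaryMask(self.values > 0, self.pixel_size_xy)
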