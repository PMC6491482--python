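"""Reading and writing of image stacks, masks and label volumes.

Supported inputs are multi-page TIFFs (one page per z-slice, RGB or
single-channel) and directories of per-slice images read in
lexicographic order. Inputs deeper than 8 bits are linearly rescaled to
the canonical 0–255 working scale using the full dtype range, so a
16-bit value of 65535 maps exactly to 255.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import BinaryMask, GrayImage, ImageStack

__all__ = [
    "read_stack",
    "extract_channel",
    "write_label_volume",
    "read_label_volume",
    "read_mask",
    "write_mask_volume",
]

DEFAULT_CHANNEL_MAP = {"membrane": 0, "nuclei": 2}

_SLICE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Linear rescale of integer/float data onto the 0–255 scale."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.max <= 255:
            return arr.astype(np.float64)
        return arr.astype(np.float64) * (255.0 / info.max)
    out = arr.astype(np.float64)
    if out.size and out.max() > 255:
        out = out * (255.0 / out.max())
    return out


def _ensure_channels(arr: np.ndarray) -> np.ndarray:
    """Normalize a page to (H, W, C)."""
    if arr.ndim == 2:
        return arr[:, :, None]
    if arr.ndim == 3:
        return arr
    raise ValueError(f"unsupported page shape {arr.shape}")


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size_xy: float = 0.345,
    voxel_depth: float = 0.432,
    reverse: bool = False,
) -> ImageStack:
    """Read a z-stack from a multi-page TIFF or a per-slice directory.

    Parameters
    ----------
    path
        Multi-page TIFF file, or a directory whose image files are the
        slices in lexicographic filename order.
    channel_map
        Role → channel index; defaults to red = membrane, blue = nuclei.
    pixel_size_xy, voxel_depth
        Voxel dimensions in µm.
    reverse
        Reverse slice order, for stacks acquired bottom-up (slice 0 must
        be the top of the spheroid for the refinement and cut-off scans).
    """
    path = Path(path)
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no slice images found in {path}")
        pages = [_ensure_channels(np.asarray(iio.imread(f))) for f in files]
    elif path.is_file():
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim == 3 and raw.shape[-1] in (3, 4) and raw.shape[0] not in (3, 4):
            # single RGB page
            raw = raw[None]
        pages = [_ensure_channels(p) for p in raw]
    else:
        raise FileNotFoundError(path)

    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    data = np.stack([_rescale_to_8bit(p) for p in pages])
    if reverse:
        data = data[::-1]
    n_channels = data.shape[3]
    for role, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ValueError(
                f"stack has {n_channels} channel(s); role {role!r} wants index {idx}"
            )
    return ImageStack(data, channel_map, pixel_size_xy, voxel_depth)


def extract_channel(stack: ImageStack, role: str, slice_index: int) -> GrayImage:
    """Pick one channel of one slice as a GrayImage (no luminance mixing)."""
    if role not in stack.channel_map:
        raise KeyError(f"unknown channel role {role!r}")
    if not 0 <= slice_index < stack.n_slices:
        raise IndexError(
            f"slice {slice_index} outside stack of {stack.n_slices} slices"
        )
    return GrayImage(stack.data[slice_index, :, :, stack.channel_map[role]])


def _label_dtype(volume: np.ndarray) -> np.dtype:
    vmax = int(volume.max()) if volume.size else 0
    return np.dtype(np.uint16 if vmax < 2**16 else np.uint32)


def write_label_volume(
    volume: np.ndarray, voxel_size: tuple[float, float, float], path: str | Path
) -> None:
    """Write an integer label volume as a multi-page TIFF.

    Labels are preserved exactly; the voxel size (µm, xyz order) is
    recorded in the image description so the volume round-trips with its
    physical calibration.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("label volume must be 3D (z, y, x)")
    if np.issubdtype(volume.dtype, np.floating):
        raise ValueError("label volume must be integer-typed")
    meta = {"voxel_size_um": list(map(float, voxel_size))}
    tifffile.imwrite(
        Path(path),
        volume.astype(_label_dtype(volume)),
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
    )


def read_label_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Read back a label volume and its voxel size (if recorded)."""
    with tifffile.TiffFile(Path(path)) as tif:
        volume = tif.asarray()
        desc = tif.pages[0].description
    if volume.ndim == 2:
        volume = volume[None]
    voxel = None
    if desc:
        try:
            voxel = tuple(json.loads(desc)["voxel_size_um"])
        except (ValueError, KeyError, TypeError):
            voxel = None
    return volume, voxel


def write_mask_volume(
    masks: list[BinaryMask], voxel_size: tuple[float, float, float], path: str | Path
) -> None:
    """Write per-slice binary masks as a 0/255 multi-page TIFF."""
    volume = np.stack([m.values.astype(np.uint8) * 255 for m in masks])
    meta = {"voxel_size_um": list(map(float, voxel_size))}
    tifffile.imwrite(
        Path(path),
        volume,
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
    )


def read_mask(path: str | Path, pixel_size_xy: float = 0.345) -> BinaryMask:
    """Read a single 2D mask image; any nonzero pixel is foreground."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    return BinaryMask(arr > 0, pixel_size_xy)
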