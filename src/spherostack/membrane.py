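"""Membrane (F-actin channel) segmentation of spheroid borders.

Per slice: adaptive thresholding, hole filling (the border mask is the
filled outer contour, internal cavities included), and removal of
objects too small to be spheroids (< 1200 µm² by default). Across
slices: an iterative inter-frame refinement deletes objects that do not
overlap the previous frame's objects by at least 75%, and a
marker-based watershed on the distance transform separates spheroids
that touch within a slice.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima, local_maxima
from skimage.segmentation import relabel_sequential, watershed

from .threshold import MIN_OBJECT_MEAN_8BIT, select_initial_threshold
from .types import BinaryMask, GrayImage, LabelMask

__all__ = [
    "segment_membrane_slice",
    "area_filter",
    "refine_stack",
    "separate_touching",
]

MIN_AREA_UM2 = 1200.0
MIN_OVERLAP = 0.75
MARKER_MIN_SEPARATION_PX = 20


def area_filter(mask: BinaryMask, min_area_um2: float = MIN_AREA_UM2) -> BinaryMask:
    """Delete connected components with area strictly below ``min_area_um2``.

    Areas are physical: pixel count × pixel_size_xy². Idempotent and
    monotone (output foreground is a subset of the input foreground).
    """
    if mask.is_empty():
        return BinaryMask(mask.values.copy(), mask.pixel_size_xy)
    labels = label(mask.values, connectivity=2)
    counts = np.bincount(labels.ravel())
    px_area = mask.pixel_size_xy**2
    keep = counts * px_area >= min_area_um2
    keep[0] = False
    return BinaryMask(keep[labels], mask.pixel_size_xy)


def intensity_filter(
    mask: BinaryMask, image: GrayImage, min_mean_8bit: float = MIN_OBJECT_MEAN_8BIT
) -> BinaryMask:
    """Delete components whose mean intensity is below ``min_mean_8bit``.

    Such regions are too dark to be real stained structures (same 0.20
    normalized-intensity notion as the cut-off frame rule); they arise
    when a slice contains no object and the threshold lands inside the
    autofluorescent background.
    """
    if mask.is_empty() or min_mean_8bit <= 0:
        return BinaryMask(mask.values.copy(), mask.pixel_size_xy)
    labels = label(mask.values, connectivity=2)
    counts = np.bincount(labels.ravel())
    sums = np.bincount(labels.ravel(), weights=image.values8.ravel())
    with np.errstate(invalid="ignore"):
        means = sums / np.maximum(counts, 1)
    keep = means >= min_mean_8bit
    keep[0] = False
    return BinaryMask(keep[labels], mask.pixel_size_xy)


def segment_membrane_slice(
    image: GrayImage,
    pixel_size_xy: float,
    min_area_um2: float = MIN_AREA_UM2,
) -> BinaryMask:
    """Segment the spheroid border in one membrane-channel slice.

    Pixels above the adaptively selected threshold are taken as
    foreground, each object is hole-filled (the spheroid region is the
    filled border, cavities included), and sub-spheroid debris is
    removed by the area filter, too-dark regions by the intensity
    filter. An empty mask is a legitimate result for slices outside
    the spheroid. The same minimum object area and darkness floor gate
    the threshold-candidate scoring, so a candidate detecting only
    sub-spheroid debris or background never wins the selection.
    """
    t = select_initial_threshold(
        image,
        min_object_area_px=min_area_um2 / pixel_size_xy**2,
        min_object_mean_8bit=MIN_OBJECT_MEAN_8BIT,
    )
    fg = image.values8 > t
    if fg.any():
        fg = ndimage.binary_fill_holes(fg)
    out = area_filter(BinaryMask(fg, pixel_size_xy), min_area_um2)
    return intensity_filter(out, image)


def refine_stack(
    masks: list[BinaryMask], min_overlap: float = MIN_OVERLAP
) -> list[BinaryMask]:
    """Iterative inter-frame refinement of per-slice membrane masks.

    Scanning forward from the first frame, each frame is realigned to
    the previous (reference) frame: every object whose overlap fraction
    with the union of the reference frame's retained objects —
    |O ∩ R| / |O|, relative to the object's own area — is strictly below
    ``min_overlap`` is deleted. The refined frame then becomes the
    reference for the next one. Leading empty frames pass through
    unchanged and the first non-empty frame starts the scan as is, so a
    stack whose top slices fall below the area filter is not wiped out.

    The output is pixelwise a subset of the input and the operation is
    idempotent on its own output.
    """
    if not masks:
        return []
    out: list[BinaryMask] = []
    ref: np.ndarray | None = None
    for m in masks:
        if ref is None:
            out.append(BinaryMask(m.values.copy(), m.pixel_size_xy))
            if m.values.any():
                ref = out[-1].values
            continue
        labels, n = ndimage.label(m.values, structure=np.ones((3, 3), dtype=int))
        kept = np.zeros_like(m.values)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            inter = np.bincount(labels.ravel(), weights=ref.ravel())[1:]
            keep_ids = np.flatnonzero(inter / sizes >= min_overlap) + 1
            kept = np.isin(labels, keep_ids)
        out.append(BinaryMask(kept, m.pixel_size_xy))
        ref = kept
    return out


def _marker_points(
    edt: np.ndarray,
    component: np.ndarray,
    min_separation: int,
    strategy: str,
    h: float,
) -> list[tuple[int, int]]:
    """Marker coordinates for one connected component.

    ``min_separation`` strategy: regional maxima of the distance
    transform, with peaks closer than ``min_separation`` px merged into
    one marker (the deeper peak wins; ties break on (row, col) for
    determinism). ``h_maxima`` strategy: h-maxima of the distance
    transform, one marker per resulting plateau.
    """
    comp_edt = np.where(component, edt, 0.0)
    if strategy == "h_maxima":
        peaks_mask = h_maxima(comp_edt, h) & component
    else:
        peaks_mask = local_maxima(comp_edt, connectivity=2) & component
    if not peaks_mask.any():
        idx = np.unravel_index(int(np.argmax(comp_edt)), comp_edt.shape)
        return [(int(idx[0]), int(idx[1]))]
    plateau_labels = label(peaks_mask, connectivity=2)
    peaks: list[tuple[float, int, int]] = []
    for region in regionprops(plateau_labels):
        rr, cc = np.round(region.centroid).astype(int)
        coords = region.coords
        # plateau representative: plateau pixel nearest its centroid
        d2 = (coords[:, 0] - rr) ** 2 + (coords[:, 1] - cc) ** 2
        r, c = coords[int(np.argmin(d2))]
        peaks.append((float(edt[r, c]), int(r), int(c)))
    peaks.sort(key=lambda p: (-p[0], p[1], p[2]))
    accepted: list[tuple[int, int]] = []
    min_sep2 = float(min_separation) ** 2
    for _, r, c in peaks:
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_sep2 for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def separate_touching(
    mask: BinaryMask,
    neighborhood_px: int = MARKER_MIN_SEPARATION_PX,
    strategy: str = "min_separation",
    h: float = 2.0,
) -> LabelMask:
    """Split fused objects with a marker-based watershed.

    Markers are extracted per input component from the Euclidean
    distance transform (see ``_marker_points``); the watershed floods
    the negated distance transform constrained to the foreground, with
    1-px watershed lines assigned to background. A component with a
    single marker is returned intact (no-split guarantee), and markers
    are found per component so disconnected inputs are never merged.
    """
    arr = mask.values
    if not arr.any():
        return LabelMask(np.zeros(arr.shape, dtype=np.int32), mask.pixel_size_xy)
    components = label(arr, connectivity=2)
    edt = ndimage.distance_transform_edt(arr)
    markers = np.zeros(arr.shape, dtype=np.int32)
    next_id = 1
    for comp_id in range(1, int(components.max()) + 1):
        comp = components == comp_id
        pts = _marker_points(edt, comp, neighborhood_px, strategy, h)
        for r, c in pts:
            markers[r, c] = next_id
            next_id += 1
    # watershed lines appear only between distinct markers, so a
    # single-marker component survives intact (no-split guarantee)
    labels = watershed(-edt, markers, mask=arr, watershed_line=True)
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32), mask.pixel_size_xy)
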