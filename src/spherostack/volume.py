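"""Cut-off frame detection and 3D label-volume assembly.

A spheroid grown on a culture surface is imaged top-down; the deepest
frames, where it contacts and spreads on the surface, are unusable for
3D reconstruction. Scanning from the first frame, a slice becomes the
cut-off frame when any of three rules fires on its border mask:

1. intensity — the mean normalized membrane-channel intensity inside
   the mask falls below 0.20 (the frame is too dark);
2. shape_difference — the mask area changes by more than 30% relative
   to the previous frame (the spheroid is starting to spread);
3. solidity — the mask solidity (area / convex area) drops below 0.60
   (the shape is too irregular to be a single spheroid).

Frames from the cut-off on are excluded from the assembled volumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .types import BinaryMask, GrayImage, LabelMask

__all__ = [
    "CutoffReport",
    "Volume3D",
    "solidity",
    "detect_cutoff_frame",
    "assemble_volume",
]

INTENSITY_THRESHOLD = 0.20
AREA_CHANGE_THRESHOLD = 0.30
SOLIDITY_THRESHOLD = 0.60

#: rule names in priority order (the reported rule at the cut-off slice
#: is the lowest-numbered satisfied condition)
RULES = ("intensity", "shape_difference", "solidity")


@dataclass
class CutoffReport:
    cutoff_index: int | None
    triggered_rule: str | None
    per_slice_metrics: list[dict] = field(default_factory=list)


@dataclass
class Volume3D:
    membrane_volume: np.ndarray
    nuclei_volume: np.ndarray
    voxel_size: tuple[float, float, float]


def solidity(mask: BinaryMask) -> float:
    """Solidity of a single-component mask: area / convex-hull area.

    Computed on the discrete pixel set (regionprops convention); the
    mask must contain exactly one connected component.
    """
    labels = label(mask.values, connectivity=2)
    n = int(labels.max())
    if n == 0:
        raise ValueError("empty mask has no solidity")
    if n > 1:
        raise ValueError(f"expected one component, found {n}")
    return float(regionprops(labels)[0].solidity)


def _largest_component_solidity(arr: np.ndarray) -> float:
    labels = label(arr, connectivity=2)
    regions = regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    return float(largest.solidity)


def detect_cutoff_frame(
    membrane_masks: list[BinaryMask],
    gray_slices: list[GrayImage],
    intensity_threshold: float = INTENSITY_THRESHOLD,
    area_change_threshold: float = AREA_CHANGE_THRESHOLD,
    solidity_threshold: float = SOLIDITY_THRESHOLD,
    growth_only: bool = False,
) -> CutoffReport:
    """Scan the stack in order and locate the first rule violation.

    ``gray_slices`` are the membrane-channel images used by the
    intensity rule (normalized [0, 1] scale). Empty masks are skipped:
    before the first non-empty mask they carry no information, and the
    area rule always compares against the previous *non-empty* mask.
    With ``growth_only`` the shape-difference rule fires on area growth
    only, not shrinkage.
    """
    if len(membrane_masks) != len(gray_slices):
        raise ValueError("masks and gray slices must align")
    report = CutoffReport(None, None, [])
    prev_area: float | None = None
    for i, (mask, gray) in enumerate(zip(membrane_masks, gray_slices)):
        if mask.is_empty():
            report.per_slice_metrics.append(
                {"mean_intensity": None, "area_px": 0, "solidity": None}
            )
            continue
        arr = mask.values
        mean_intensity = float(gray.normalized[arr].mean())
        area = float(arr.sum())
        sol = _largest_component_solidity(arr)
        report.per_slice_metrics.append(
            {"mean_intensity": mean_intensity, "area_px": int(area), "solidity": sol}
        )
        if report.cutoff_index is not None:
            continue  # keep collecting metrics past the cut-off
        fired: str | None = None
        if mean_intensity < intensity_threshold:
            fired = "intensity"
        elif prev_area is not None:
            change = (area - prev_area) / prev_area
            if not growth_only:
                change = abs(change)
            if change > area_change_threshold:
                fired = "shape_difference"
        if fired is None and sol < solidity_threshold:
            fired = "solidity"
        if fired is not None:
            report.cutoff_index = i
            report.triggered_rule = fired
        prev_area = area
    return report


def assemble_volume(
    membrane_labels: list[LabelMask],
    nuclei_labels: list[LabelMask],
    cutoff: CutoffReport,
    voxel: tuple[float, float, float],
) -> Volume3D:
    """Stack per-slice labels into 3D volumes, truncated at the cut-off.

    Slices 0..cutoff_index-1 are kept (all slices when no cut-off was
    found); labels are copied bit-exactly, per-slice.
    """
    if len(membrane_labels) != len(nuclei_labels):
        raise ValueError("membrane and nuclei label lists must align")
    depth = cutoff.cutoff_index if cutoff.cutoff_index is not None else len(membrane_labels)
    mem = np.stack([m.values for m in membrane_labels[:depth]]) if depth else np.zeros(
        (0, 0, 0), dtype=np.int32
    )
    nuc = np.stack([m.values for m in nuclei_labels[:depth]]) if depth else np.zeros(
        (0, 0, 0), dtype=np.int32
    )
    return Volume3D(mem, nuc, tuple(voxel))
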