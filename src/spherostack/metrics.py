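"""Pixel-level segmentation agreement between a manual (reference) mask
and an automatic mask: recall, precision, F1 and Jaccard, plus object
counting agreement and an inner/outer shell stratification of the
scores (errors near the spheroid border vs. in its core).

Conventions: TP = pixels in both masks, FN = reference-only pixels,
FP = automatic-only pixels; recall = TP/(TP+FN), precision =
TP/(TP+FP), F1 = harmonic mean of the two, Jaccard = TP/(TP+FP+FN)
(intersection over union). Degenerate denominators (an empty mask on
either side) yield 0 with an explicit flag rather than an error, so
blank slices survive batch evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .types import BinaryMask

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "scores",
    "evaluate_masks",
    "shell_scores",
    "count_agreement",
]

DEFAULT_SHELL_WIDTH_UM = 20.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class EvalReport:
    recall: float
    precision: float
    f1: float
    jaccard: float
    n_objects_manual: int | None = None
    n_objects_auto: int | None = None
    degenerate: bool = False


def confusion(manual: BinaryMask, automatic: BinaryMask) -> ConfusionCounts:
    """Exact pixel-set confusion counts between two aligned masks."""
    a, b = manual.values, automatic.values
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(b & ~a))
    fn = int(np.count_nonzero(a & ~b))
    return ConfusionCounts(tp, fp, fn)


def scores(
    counts: ConfusionCounts,
    n_objects_manual: int | None = None,
    n_objects_auto: int | None = None,
) -> EvalReport:
    """Recall/precision/F1/Jaccard from confusion counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    degenerate = (tp + fn == 0) or (tp + fp == 0)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2.0 * recall * precision / (recall + precision)
        if recall + precision > 0
        else 0.0
    )
    jaccard = tp / (tp + fp + fn) if tp + fp + fn else 0.0
    return EvalReport(
        recall, precision, f1, jaccard, n_objects_manual, n_objects_auto, degenerate
    )


def evaluate_masks(manual: BinaryMask, automatic: BinaryMask) -> EvalReport:
    """Convenience: confusion + scores + 8-connected object counts."""
    rep = scores(
        confusion(manual, automatic),
        n_objects_manual=int(label(manual.values, connectivity=2).max()),
        n_objects_auto=int(label(automatic.values, connectivity=2).max()),
    )
    return rep


def _restricted(manual: BinaryMask, automatic: BinaryMask, region: np.ndarray) -> EvalReport:
    psz = manual.pixel_size_xy
    return scores(
        confusion(
            BinaryMask(manual.values & region, psz),
            BinaryMask(automatic.values & region, psz),
        )
    )


def shell_scores(
    manual: BinaryMask,
    automatic: BinaryMask,
    membrane: BinaryMask,
    shell_width_um: float = DEFAULT_SHELL_WIDTH_UM,
) -> tuple[EvalReport, EvalReport]:
    """Scores stratified into the spheroid's core and its outer shell.

    The outer region is the band of membrane pixels within
    ``shell_width_um`` of the membrane boundary (via the Euclidean
    distance transform); the inner region is the rest of the membrane.
    Returns (inner, outer) reports; a shell wider than the object
    radius leaves the inner region empty, flagged degenerate.
    """
    if membrane.is_empty():
        raise ValueError("membrane mask is empty")
    shell_px = shell_width_um / membrane.pixel_size_xy
    depth = ndimage.distance_transform_edt(membrane.values)
    outer = membrane.values & (depth <= shell_px)
    inner = membrane.values & (depth > shell_px)
    return (
        _restricted(manual, automatic, inner),
        _restricted(manual, automatic, outer),
    )


def count_agreement(
    manual_count: int, auto_count: int
) -> tuple[int, float | None]:
    """Signed count difference (auto − manual) and its relative error.

    The relative error is None when the manual count is zero.
    """
    if manual_count < 0 or auto_count < 0:
        raise ValueError("counts must be non-negative")
    diff = auto_count - manual_count
    rel = diff / manual_count if manual_count > 0 else None
    return diff, rel
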