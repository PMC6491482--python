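"""Adaptive object-based threshold selection from the histogram's
progressive weighted mean (PWM) curve.

The PWM curve assigns to every grayscale class P (0–255) the weighted
mean of all histogram bins up to P:

    pwm[P] = sum_{i<=P} w_i * i / sum_{i<=P} w_i

with w_i the count of class i. The curve tracks the shape of the
intensity distribution, and its inflection points — estimated from a
10th-order polynomial fit — mark local stability points of the
histogram that serve as candidate thresholds. Each candidate is scored
by the spread (standard deviation) of the intensities of the pixels it
detects as objects; the candidate with the most homogeneous objects
(lowest spread) becomes the initial threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq
from skimage.filters import threshold_otsu
from skimage.measure import label

from .types import GrayImage

__all__ = [
    "ThresholdCandidate",
    "compute_histogram",
    "pwm_curve",
    "candidate_thresholds",
    "score_candidate",
    "select_initial_threshold",
    "plot_threshold_diagnostics",
]

logger = logging.getLogger(__name__)

POLY_DEGREE = 10
#: grid density for locating sign changes of the fitted second derivative
_GRID_POINTS = 2551


@dataclass(frozen=True)
class ThresholdCandidate:
    """A candidate threshold with its object-homogeneity score."""

    threshold: int
    object_intensity_std: float  # NaN when no foreground pixel
    n_objects: int
    n_object_pixels: int = 0
    object_intensity_mean: float = float("nan")

    @property
    def valid(self) -> bool:
        return self.n_objects > 0 and np.isfinite(self.object_intensity_std)


def compute_histogram(image: GrayImage) -> np.ndarray:
    """256-bin histogram of the image on the 0–255 scale.

    Intensities are rounded to the nearest class; the total count equals
    the pixel count of the image.
    """
    classes = np.clip(np.rint(image.values8), 0, 255).astype(np.int64)
    return np.bincount(classes.ravel(), minlength=256)


def pwm_curve(hist: np.ndarray) -> np.ndarray:
    """Progressive weighted mean of a 256-bin histogram.

    Classes before the first nonzero bin (empty prefix, undefined mean)
    are assigned 0; the resulting curve is monotone non-decreasing and
    bounded by 0 <= pwm[P] <= P.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is all zero")
    if hist.min() < 0:
        raise ValueError("histogram counts must be non-negative")
    x = np.arange(256, dtype=np.float64)
    num = np.cumsum(hist * x)
    den = np.cumsum(hist)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return values


def candidate_thresholds(curve: np.ndarray) -> list[int]:
    """Inflection points of the degree-10 polynomial fit to the curve.

    The fit is least squares over all 256 classes with the abscissa
    mapped to [-1, 1] (a raw degree-10 Vandermonde on 0..255 is
    hopelessly ill-conditioned). Inflections are the real roots of the
    fitted polynomial's second derivative inside [0, 255] at which the
    concavity actually changes sign; even-multiplicity touches are
    discarded. Returned thresholds are rounded to integer classes,
    deduplicated and sorted. A degenerate (e.g. constant) curve yields
    an empty list rather than an error.
    """
    curve = np.asarray(curve, dtype=np.float64)
    if curve.shape != (256,):
        raise ValueError("PWM curve must have 256 values")
    if curve.max() - curve.min() == 0.0:
        return []  # constant curve has no inflection
    x = np.arange(256, dtype=np.float64)
    try:
        poly = Polynomial.fit(x, curve, POLY_DEGREE, domain=[0.0, 255.0])
    except (np.linalg.LinAlgError, ValueError):
        return []
    d2 = poly.deriv(2)
    grid = np.linspace(0.0, 255.0, _GRID_POINTS)
    vals = d2(grid)
    scale = float(np.abs(vals).max())
    if scale == 0.0 or not np.isfinite(scale):
        return []
    # treat numerically-zero stretches as zero so fit noise on flat curves
    # does not fabricate inflections
    sign = np.sign(vals)
    sign[np.abs(vals) < 1e-9 * scale] = 0

    roots: list[float] = []
    nz = np.flatnonzero(sign != 0)
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] * sign[b] < 0:
            try:
                r = brentq(d2, grid[a], grid[b])
            except ValueError:
                r = 0.5 * (grid[a] + grid[b])
            roots.append(float(r))
    out = sorted({int(np.clip(np.rint(r), 0, 255)) for r in roots})
    return out


def score_candidate(
    image: GrayImage, threshold: int, min_object_area_px: float = 0.0
) -> ThresholdCandidate:
    """Score a threshold by the pooled intensity spread of its objects.

    The image is binarized at intensity strictly greater than the
    threshold, connected components are labelled (8-connectivity), and
    the standard deviation (sample, n-1) of all pixel intensities
    belonging to detected objects is the score. With
    ``min_object_area_px`` > 0, components smaller than that are not
    objects (they are debris below the size of the structures being
    detected) and contribute neither to the count nor to the spread; a
    threshold detecting no object is an invalid candidate (NaN score)
    rather than an error.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in 0..255")
    fg = image.values8 > threshold
    if not fg.any():
        return ThresholdCandidate(int(threshold), float("nan"), 0)
    labels = label(fg, connectivity=2)
    if min_object_area_px > 0:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = counts >= min_object_area_px
        if not keep.any():
            return ThresholdCandidate(int(threshold), float("nan"), 0, 0)
        n_objects = int(keep.sum())
        fg = keep[labels]
    else:
        n_objects = int(labels.max())
    pixels = image.values8[fg]
    std = float(pixels.std(ddof=1)) if pixels.size > 1 else 0.0
    return ThresholdCandidate(
        int(threshold), std, n_objects, int(pixels.size), float(pixels.mean())
    )


MAX_FOREGROUND_FRACTION = 0.95
#: detections with a mean normalized intensity below 0.10 are background,
#: not stained structures; deliberately below the 0.20 cut-off intensity
#: rule so genuinely dim (contact) frames still reach the cut-off scan
MIN_OBJECT_MEAN_8BIT = 0.10 * 255.0


def select_initial_threshold(
    image: GrayImage,
    min_object_area_px: float = 0.0,
    max_foreground_fraction: float = MAX_FOREGROUND_FRACTION,
    min_object_mean_8bit: float = 0.0,
    return_candidates: bool = False,
) -> int | tuple[int, list[ThresholdCandidate]]:
    """Pick the candidate threshold giving the most homogeneous objects.

    Among the inflection-point candidates of the PWM curve, the one with
    the lowest pooled object-intensity standard deviation wins; ties go
    to the smaller (more inclusive) threshold. ``min_object_area_px``
    is forwarded to the scoring step, so candidates that detect only
    sub-object debris are excluded from the competition; likewise a
    candidate whose objects cover more than ``max_foreground_fraction``
    of the field, or that lies below the histogram's dominant mode, has
    merely swallowed the background (objects are by definition brighter
    than a threshold above the background peak) and is not a detection;
    with ``min_object_mean_8bit`` > 0, neither is one whose objects are
    on average darker than that (on the 0–255 scale).
    When no valid candidate exists (flat or degenerate histogram, or a
    slice with no object at all) the global Otsu threshold is used as a
    fallback and a warning is logged.
    """
    hist = compute_histogram(image)
    nonzero = np.flatnonzero(hist)
    if nonzero.size <= 1:
        # constant image: any threshold >= the single class gives empty
        # foreground; return that class so binarization is empty
        t = int(nonzero[0]) if nonzero.size else 0
        return (t, []) if return_candidates else t
    curve = pwm_curve(hist)
    cands = candidate_thresholds(curve)
    scored = [score_candidate(image, t, min_object_area_px) for t in cands]
    max_px = max_foreground_fraction * image.values8.size
    mode_bin = int(np.argmax(hist))
    valid = [
        c
        for c in scored
        if c.valid
        and c.n_object_pixels <= max_px
        and c.threshold >= mode_bin
        and (min_object_mean_8bit <= 0 or c.object_intensity_mean >= min_object_mean_8bit)
    ]
    if valid:
        best = min(valid, key=lambda c: (c.object_intensity_std, c.threshold))
        t = best.threshold
    else:
        t = int(np.clip(np.rint(threshold_otsu(hist=hist)), 0, 255))
        logger.warning(
            "no valid PWM candidate threshold; falling back to Otsu (t=%d)", t
        )
    return (t, scored) if return_candidates else t


def plot_threshold_diagnostics(image: GrayImage, path) -> None:
    """Write a diagnostic PNG: histogram, PWM curve, candidates, choice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = compute_histogram(image)
    curve = pwm_curve(hist)
    chosen, cands = select_initial_threshold(image, return_candidates=True)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].bar(np.arange(256), hist, width=1.0, color="gray")
    axes[0].set_title("histogram")
    axes[1].plot(curve, color="navy")
    for c in cands:
        axes[1].axvline(c.threshold, color="red", ls=":", lw=0.8)
    axes[1].axvline(chosen, color="green", lw=1.5)
    axes[1].set_title("PWM curve + candidates")
    axes[2].imshow(image.values8 > chosen, cmap="gray")
    axes[2].set_title(f"mask at t={chosen}")
    axes[2].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
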