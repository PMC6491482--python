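"""Synthetic spheroid stacks with exact ground truth.

The generator emulates a confocal z-stack of a spheroid grown on a
culture surface and imaged top-down: a hemispherical dome whose slice
radius grows with depth, a membrane (F-actin) channel rendered as a
filled disc with a brighter cortical rim, and a nuclei (DAPI) channel
of non-overlapping ellipses packed inside the disc, a configurable
fraction of them fused in touching pairs to exercise the watershed.
Degradations follow the qualitative behaviour of real fluorescence
data: Gaussian read noise, slice-to-slice multiplicative intensity
variation, and a smooth low-frequency background standing in for
out-of-focus autofluorescence. All randomness flows from a single
seeded generator, so stacks are bit-reproducible.

``spread_slice`` emulates the first contact with the culture surface:
from that slice on the disc dilates abruptly into a wider ellipse
(area jump ≳ 45%), which is what the cut-off scan's shape-difference
rule looks for.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .types import BinaryMask, GrayImage, ImageStack, LabelMask

__all__ = [
    "SpheroidSpec",
    "GroundTruth",
    "generate_stack",
    "generate_fused_pair_image",
    "engineered_cutoff_stack",
]


@dataclass
class SpheroidSpec:
    """Parameters of one synthetic spheroid stack.

    Defaults mirror a typical acquisition: 0.345 × 0.345 × 0.432 µm
    voxels and a ~30 µm-radius spheroid filling a 256×256 field of
    view; slice 0 is the top of the dome.
    """

    radius_um: float = 30.0
    center: tuple[int, int] | None = None  # (row, col); image centre if None
    n_slices: int = 64
    height: int = 256
    width: int = 256
    pixel_size_xy: float = 0.345
    voxel_depth: float = 0.432
    nuclei_per_slice: tuple[int, int] = (20, 60)
    nucleus_axes_um: tuple[float, float] = (3.2, 4.0)  # semi-axes range
    membrane_intensity: float = 130.0
    membrane_variation: float = 0.10
    rim_intensity: float = 225.0
    rim_width_um: float = 1.5
    nuclei_intensity: float = 190.0
    nuclei_variation: float = 0.02
    background_level: float = 10.0
    noise_sd: float = 8.0
    autofluorescence_gradient: float = 12.0
    psf_sigma_px: float = 1.0  # optical blur of structure edges
    fused_fraction: float = 0.10
    spread_slice: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um / self.pixel_size_xy * 2 >= min(self.height, self.width):
            raise ValueError("spheroid does not fit in the frame")
        for name in ("membrane_intensity", "nuclei_intensity", "rim_intensity",
                     "background_level"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} outside 0..255")


@dataclass
class GroundTruth:
    membrane_masks: list[BinaryMask]
    nuclei_labels: list[LabelMask]
    true_counts: list[int]
    true_cutoff: int | None = None

    def nuclei_mask(self, z: int) -> BinaryMask:
        return self.nuclei_labels[z].binary()


def _nucleus_footprint(
    h: int,
    w: int,
    center: tuple[float, float],
    axes: tuple[float, float],
    rot: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window coordinates and squared elliptical radius of one nucleus.

    Returns (rows, cols, q) over a local window, with q the squared
    normalized elliptical radius: q <= 1 is the nucleus footprint.
    """
    a, b = axes
    r0, c0 = center
    win = int(np.ceil(1.5 * max(a, b)))
    rlo, rhi = max(int(r0) - win, 0), min(int(r0) + win + 1, h)
    clo, chi = max(int(c0) - win, 0), min(int(c0) + win + 1, w)
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    dy, dx = yy - r0, xx - c0
    u = dy * math.cos(rot) - dx * math.sin(rot)
    v = dy * math.sin(rot) + dx * math.cos(rot)
    q = (u / a) ** 2 + (v / b) ** 2
    return yy, xx, q


def _disc(h: int, w: int, center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma: float = 24.0) -> np.ndarray:
    """Zero-mean smooth random field normalized to peak amplitude 1."""
    f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    span = max(np.abs(f).max(), 1e-12)
    return f / span


def _texture(rng: np.random.Generator, h: int, w: int, sigma: float = 1.3) -> np.ndarray:
    """Fine-grained zero-mean texture, unit standard deviation.

    Emulates the granularity of chromatin (DAPI) and actin bundles
    (phalloidin): correlated over a few pixels, so the upper tail of a
    stained region is made of granules far smaller than any real
    object. Without this, synthetic structures would be unrealistically
    flat and a high threshold could carve a homogeneous "object" out of
    the brightest stretch of real signal.
    """
    f = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    return f / max(float(f.std()), 1e-12)


def _slice_radius_px(spec: SpheroidSpec, z: int) -> float:
    """Hemisphere profile: dome apex at slice 0, equator at the surface."""
    depth = min(z * spec.voxel_depth, spec.radius_um)
    r_um = math.sqrt(max(spec.radius_um**2 - (spec.radius_um - depth) ** 2, 0.0))
    return r_um / spec.pixel_size_xy


def _place_nuclei(
    rng: np.random.Generator,
    spec: SpheroidSpec,
    center: tuple[float, float],
    disc_radius_px: float,
    target: int,
) -> list[dict]:
    """Dart-throwing placement of nucleus ellipses inside the disc.

    Non-mate centers keep a separation of at least twice the largest
    semi-axis (plus margin) so nuclei never fuse by accident; a
    ``fused_fraction`` of placements becomes a touching pair. When the
    disc cannot host the requested number, fewer nuclei are placed and
    the true count reflects what was actually drawn.
    """
    ax_lo, ax_hi = spec.nucleus_axes_um
    max_ax_px = ax_hi / spec.pixel_size_xy
    margin = disc_radius_px - max_ax_px - 2.0
    nuclei: list[dict] = []
    if margin <= ax_lo / spec.pixel_size_xy:
        return nuclei
    min_sep = 2.0 * max_ax_px + 3.0
    positions: list[tuple[float, float]] = []

    def far_enough(r: float, c: float, exempt: int | None = None) -> bool:
        for j, (pr, pc) in enumerate(positions):
            if j == exempt:
                continue
            if (r - pr) ** 2 + (c - pc) ** 2 < min_sep**2:
                return False
        return True

    attempts = 0
    while len(nuclei) < target and attempts < 60 * target:
        attempts += 1
        rho = margin * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r = center[0] + rho * math.sin(theta)
        c = center[1] + rho * math.cos(theta)
        if not far_enough(r, c):
            continue
        a = rng.uniform(ax_lo, ax_hi) / spec.pixel_size_xy
        b = rng.uniform(ax_lo, ax_hi) / spec.pixel_size_xy
        rot = rng.uniform(0.0, math.pi)
        nuclei.append({"center": (r, c), "axes": (a, b), "rot": rot})
        positions.append((r, c))
        # occasionally attach a touching mate to exercise the watershed
        if (
            len(nuclei) < target
            and rng.uniform() < spec.fused_fraction
        ):
            for _ in range(12):
                phi = rng.uniform(0.0, 2.0 * math.pi)
                a2 = rng.uniform(ax_lo, ax_hi) / spec.pixel_size_xy
                b2 = rng.uniform(ax_lo, ax_hi) / spec.pixel_size_xy
                d = 0.95 * (min(a, b) + min(a2, b2))
                mr, mc = r + d * math.sin(phi), c + d * math.cos(phi)
                if (mr - center[0]) ** 2 + (mc - center[1]) ** 2 > margin**2:
                    continue
                if not far_enough(mr, mc, exempt=len(positions) - 1):
                    continue
                nuclei.append(
                    {"center": (mr, mc), "axes": (a2, b2), "rot": rng.uniform(0.0, math.pi)}
                )
                positions.append((mr, mc))
                break
    return nuclei


def _spread_mask(h: int, w: int, center: tuple[float, float], r_px: float) -> np.ndarray:
    """Surface-contact shape: the disc flattened into a wider ellipse.

    Area ratio vs the disc is 1.10 × 1.20 = 1.32: above the 30%
    area-jump cut-off rule, yet the old disc still makes up >75% of the
    new shape, so the inter-frame refinement does not delete it.
    """
    rr, cc = draw_ellipse(center[0], center[1], 1.10 * r_px, 1.20 * r_px, shape=(h, w))
    out = np.zeros((h, w), dtype=bool)
    out[rr, cc] = True
    return out


def generate_stack(spec: SpheroidSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a hemispherical spheroid stack and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    center = spec.center or (h / 2.0, w / 2.0)
    psz = spec.pixel_size_xy
    rim_px = max(spec.rim_width_um / psz, 1.0)
    lo, hi = spec.nuclei_per_slice

    # one background field per stack: out-of-focus autofluorescence
    background = spec.background_level + spec.autofluorescence_gradient * (
        0.5 * (_smooth_field(rng, h, w, sigma=48.0) + 1.0)
    )

    data = np.zeros((spec.n_slices, h, w, 3))
    membrane_masks: list[BinaryMask] = []
    nuclei_labels: list[LabelMask] = []
    true_counts: list[int] = []

    for z in range(spec.n_slices):
        r_px = _slice_radius_px(spec, z)
        spreading = spec.spread_slice is not None and z >= spec.spread_slice
        if r_px < 1.0:
            disc = np.zeros((h, w), dtype=bool)
        elif spreading:
            disc = _spread_mask(h, w, center, r_px)
        else:
            disc = _disc(h, w, center, r_px)

        # membrane channel: textured actin interior + bright cortical rim
        tex = _texture(rng, h, w)
        variation = (
            1.0
            + spec.membrane_variation * _smooth_field(rng, h, w)
            + 1.8 * spec.membrane_variation * tex
        )
        red = background.copy()
        if disc.any():
            # at surface contact the actin spreads thin: frames dim sharply
            dim = 0.30 if spreading else 1.0
            interior = dim * spec.membrane_intensity * variation
            red[disc] = interior[disc]
            edt = ndimage.distance_transform_edt(disc)
            rim = disc & (edt <= rim_px)
            red[rim] = (dim * spec.rim_intensity * (1.0 + 0.6 * spec.membrane_variation * tex))[rim]
        red = ndimage.gaussian_filter(red, spec.psf_sigma_px)
        red = np.clip(red + rng.normal(0.0, spec.noise_sd, (h, w)), 0, 255)

        # nuclei channel: soft-edged elliptical blobs over dim background
        blue = 0.6 * spec.background_level + 0.3 * (background - spec.background_level)
        blue = np.broadcast_to(blue, (h, w)).copy()
        labels = np.zeros((h, w), dtype=np.int32)
        target = int(rng.integers(lo, hi + 1))
        placed = _place_nuclei(rng, spec, center, r_px, target) if disc.any() else []
        chromatin = 1.0 + 0.04 * _texture(rng, h, w, sigma=1.1)
        for idx, nuc in enumerate(placed, start=1):
            peak = spec.nuclei_intensity * (
                1.0 + spec.nuclei_variation * rng.uniform(-1.0, 1.0)
            )
            yy, xx, q = _nucleus_footprint(
                h, w, nuc["center"], nuc["axes"], nuc["rot"]
            )
            footprint = q <= 1.0
            # graded DNA density: bright centre, dimmer periphery, so a
            # threshold anywhere inside the nucleus band extracts one
            # connected centred core per nucleus
            grade = np.clip(1.15 - 0.30 * q, 0.0, None)
            body = np.clip(peak * grade * chromatin[yy, xx], 0, 255)
            blue[yy, xx] = np.where(footprint, np.maximum(blue[yy, xx], body), blue[yy, xx])
            free = footprint & (labels[yy, xx] == 0)  # earlier nucleus wins overlaps
            labels[yy[free], xx[free]] = idx
        blue = ndimage.gaussian_filter(blue, spec.psf_sigma_px)
        blue = np.clip(blue + rng.normal(0.0, spec.noise_sd, (h, w)), 0, 255)

        green = np.clip(rng.normal(4.0, 2.0, (h, w)), 0, 255)
        data[z, :, :, 0] = red
        data[z, :, :, 1] = green
        data[z, :, :, 2] = blue
        membrane_masks.append(BinaryMask(disc, psz))
        nuclei_labels.append(LabelMask(labels, psz))
        true_counts.append(len(placed))

    stack = ImageStack(
        data,
        {"membrane": 0, "nuclei": 2},
        spec.pixel_size_xy,
        spec.voxel_depth,
    )
    truth = GroundTruth(membrane_masks, nuclei_labels, true_counts, spec.spread_slice)
    return stack, truth


def generate_fused_pair_image(
    r_px: int,
    center_distance_px: float,
    seed: int = 0,
    foreground: float = 200.0,
    background: float = 15.0,
    noise_sd: float = 5.0,
) -> tuple[GrayImage, dict]:
    """Two overlapping bright discs forming one connected component.

    Requires 0 < center distance < 2r so fusion is guaranteed. Returns
    the noisy image and the truth: both disc masks, the two centers and
    the component count of the union (2 when the discs are disjoint,
    1 when fused).
    """
    if not 0 < center_distance_px:
        raise ValueError("center distance must be positive")
    rng = np.random.default_rng(seed)
    pad = 12
    h = int(2 * r_px + 2 * pad)
    w = int(2 * r_px + center_distance_px + 2 * pad)
    c1 = (h / 2.0, pad + r_px)
    c2 = (h / 2.0, pad + r_px + center_distance_px)
    d1 = _disc(h, w, c1, r_px)
    d2 = _disc(h, w, c2, r_px)
    union = d1 | d2
    img = np.full((h, w), background)
    img[union] = foreground
    img = np.clip(img + rng.normal(0.0, noise_sd, (h, w)), 0, 255)
    n_components = int(ndimage.label(union)[1])
    truth = {
        "discs": (d1, d2),
        "centers": (c1, c2),
        "n_true_objects": 2,
        "n_components": n_components,
        "fused": n_components == 1,
    }
    return GrayImage(img), truth


def _cross_mask(h: int, w: int, center: tuple[int, int], arm: int, width: int) -> np.ndarray:
    """Thin plus-shape; solidity ≈ 0.4, far below the 0.60 rule."""
    out = np.zeros((h, w), dtype=bool)
    r, c = center
    out[r - width // 2 : r + width // 2, c - arm // 2 : c + arm // 2] = True
    out[r - arm // 2 : r + arm // 2, c - width // 2 : c + width // 2] = True
    return out


def engineered_cutoff_stack(
    kind: str,
    n_slices: int = 12,
    trigger_slice: int = 6,
    pixel_size_xy: float = 0.345,
    shape: tuple[int, int] = (160, 160),
) -> tuple[list[BinaryMask], list[GrayImage], int, str]:
    """Mask/image stacks engineered to trip exactly one cut-off rule.

    ``kind``:
      - "intensity": constant discs; the trigger slice dims to a mean
        in-mask intensity of 0.15 (< 0.20);
      - "area": disc areas grow ~4%/slice, then jump ~45% at the
        trigger (> 30%);
      - "solidity": discs replaced by a thin cross of matching area at
        the trigger (solidity ≈ 0.4 < 0.60, area change ≈ 1%).

    Returns (masks, gray slices, trigger index, expected rule name).
    """
    h, w = shape
    center = (h // 2, w // 2)
    bright, dim, bg = 140.0, 0.15 * 255.0, 12.0
    masks: list[BinaryMask] = []
    grays: list[GrayImage] = []

    def render(mask: np.ndarray, value: float) -> GrayImage:
        img = np.full((h, w), bg)
        img[mask] = value
        return GrayImage(img)

    if kind == "intensity":
        rule = "intensity"
        for i in range(n_slices):
            mask = _disc(h, w, center, 40.0)
            masks.append(BinaryMask(mask, pixel_size_xy))
            grays.append(render(mask, dim if i == trigger_slice else bright))
    elif kind == "area":
        rule = "shape_difference"
        radius = 30.0
        for i in range(n_slices):
            if i == trigger_slice:
                radius *= math.sqrt(1.45)
            elif i > 0:
                radius *= 1.02
            mask = _disc(h, w, center, radius)
            masks.append(BinaryMask(mask, pixel_size_xy))
            grays.append(render(mask, bright))
    elif kind == "solidity":
        rule = "solidity"
        disc_r = 17.0  # area ≈ 908 px, matching the cross below (Δ ≈ 1%)
        for i in range(n_slices):
            if i >= trigger_slice:
                mask = _cross_mask(h, w, center, arm=60, width=8)
            else:
                mask = _disc(h, w, center, disc_r)
            masks.append(BinaryMask(mask, pixel_size_xy))
            grays.append(render(mask, bright))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return masks, grays, trigger_slice, rule
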