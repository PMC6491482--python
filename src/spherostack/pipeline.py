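"""End-to-end pipeline orchestration and batch evaluation.

The pipeline runs the three processing stages in order: membrane
segmentation over all slices (adaptive threshold, hole filling, area
filter, inter-frame refinement, watershed separation), nucleus
detection gated by the refined membrane masks, and cut-off detection
plus 3D volume assembly. Results can be held in memory or written to
an output directory together with the resolved configuration, so a run
is fully reproducible from its artefacts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.measure import regionprops

from . import membrane as mem
from . import metrics as met
from . import nuclei as nuc
from . import volume as vol
from .stack_io import (
    DEFAULT_CHANNEL_MAP,
    extract_channel,
    read_mask,
    read_stack,
    write_label_volume,
    write_mask_volume,
)
from .threshold import select_initial_threshold
from .types import BinaryMask, ImageStack, LabelMask

__all__ = ["RunConfig", "SegmentationResult", "run_pipeline", "save_result", "run_eval"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the reference operating
    point (1200 µm² area filter, 75% overlap, 20 px marker separation,
    cut-off rules 0.20 / 30% / 0.60)."""

    pixel_size_xy: float = 0.345
    voxel_depth: float = 0.432
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    reverse_stack: bool = False
    phal_min_area_um2: float = mem.MIN_AREA_UM2
    phal_min_overlap: float = mem.MIN_OVERLAP
    phal_marker_min_separation_px: int = mem.MARKER_MIN_SEPARATION_PX
    phal_marker_strategy: str = "min_separation"
    phal_h_maxima_h: float = 2.0
    dapi_min_area_um2: float = nuc.NUCLEUS_MIN_AREA_UM2
    dapi_scoring_min_area_um2: float = nuc.NUCLEUS_SCORING_MIN_AREA_UM2
    dapi_marker_min_separation_px: int = nuc.NUCLEUS_MARKER_SEPARATION_PX
    cutoff_intensity: float = vol.INTENSITY_THRESHOLD
    cutoff_area_change: float = vol.AREA_CHANGE_THRESHOLD
    cutoff_solidity: float = vol.SOLIDITY_THRESHOLD
    cutoff_growth_only: bool = False
    metrics_shell_width_um: float = met.DEFAULT_SHELL_WIDTH_UM

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SegmentationResult:
    """Everything one pipeline run produces, in memory."""

    membrane_masks: list[BinaryMask]  # refined binary masks
    membrane_labels: list[LabelMask]  # after watershed separation
    nuclei: list[nuc.NucleiResult]
    cutoff: vol.CutoffReport
    volume: vol.Volume3D
    thresholds: list[int]  # per-slice membrane threshold
    timings: dict = field(default_factory=dict)

    @property
    def nuclei_counts(self) -> list[int]:
        return [r.count for r in self.nuclei]


def run_pipeline(stack: ImageStack, config: RunConfig | None = None) -> SegmentationResult:
    """Run membrane → nuclei → cut-off/volume on one stack."""
    cfg = config or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    gray_membrane = [
        extract_channel(stack, "membrane", z) for z in range(stack.n_slices)
    ]
    raw_masks = []
    thresholds = []
    min_area_px = cfg.phal_min_area_um2 / stack.pixel_size_xy**2
    for z, g in enumerate(gray_membrane):
        t = select_initial_threshold(
            g,
            min_object_area_px=min_area_px,
            min_object_mean_8bit=mem.MIN_OBJECT_MEAN_8BIT,
        )
        thresholds.append(t)
        fg = g.values8 > t
        if fg.any():
            fg = ndimage.binary_fill_holes(fg)
        filtered = mem.area_filter(
            BinaryMask(fg, stack.pixel_size_xy), cfg.phal_min_area_um2
        )
        raw_masks.append(mem.intensity_filter(filtered, g))
    # The stack begins above the spheroid dome: anything detected before
    # the first bright frame (mean in-mask intensity >= the cut-off
    # darkness threshold) is background, not the spheroid. Dark frames
    # *after* the dome are kept — they are surface-contact candidates
    # for the cut-off scan.
    first_bright = next(
        (
            z
            for z, (m, g) in enumerate(zip(raw_masks, gray_membrane))
            if not m.is_empty()
            and g.normalized[m.values].mean() >= cfg.cutoff_intensity
        ),
        len(raw_masks),
    )
    empty = np.zeros((stack.height, stack.width), dtype=bool)
    for z in range(first_bright):
        raw_masks[z] = BinaryMask(empty.copy(), stack.pixel_size_xy)
    refined = mem.refine_stack(raw_masks, cfg.phal_min_overlap)
    membrane_labels = [
        mem.separate_touching(
            m,
            neighborhood_px=cfg.phal_marker_min_separation_px,
            strategy=cfg.phal_marker_strategy,
            h=cfg.phal_h_maxima_h,
        )
        for m in refined
    ]
    timings["membrane_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    nuclei_results = []
    for z in range(stack.n_slices):
        g = extract_channel(stack, "nuclei", z)
        nuclei_results.append(
            nuc.segment_nuclei_slice(
                g,
                refined[z],
                min_area_um2=cfg.dapi_min_area_um2,
                scoring_min_area_um2=cfg.dapi_scoring_min_area_um2,
                marker_min_separation_px=cfg.dapi_marker_min_separation_px,
                strategy=cfg.phal_marker_strategy,
            )
        )
    timings["nuclei_s"] = time.perf_counter() - t0

    # the cut-off scan runs on the pre-refinement masks: a surface-contact
    # frame (sudden spread) is exactly what the 75% overlap rule deletes,
    # so the refined masks can never exhibit the >30% area jump the
    # shape-difference rule looks for
    t0 = time.perf_counter()
    cutoff = vol.detect_cutoff_frame(
        raw_masks,
        gray_membrane,
        intensity_threshold=cfg.cutoff_intensity,
        area_change_threshold=cfg.cutoff_area_change,
        solidity_threshold=cfg.cutoff_solidity,
        growth_only=cfg.cutoff_growth_only,
    )
    volume3d = vol.assemble_volume(
        membrane_labels,
        [r.labels for r in nuclei_results],
        cutoff,
        (stack.pixel_size_xy, stack.pixel_size_xy, stack.voxel_depth),
    )
    timings["rendering_s"] = time.perf_counter() - t0
    logger.info(
        "pipeline done: %d slices, cutoff=%s (%s), timings=%s",
        stack.n_slices,
        cutoff.cutoff_index,
        cutoff.triggered_rule,
        {k: round(v, 2) for k, v in timings.items()},
    )
    return SegmentationResult(
        refined, membrane_labels, nuclei_results, cutoff, volume3d, thresholds, timings
    )


def _nuclei_table(result: SegmentationResult, pixel_size_xy: float) -> pd.DataFrame:
    rows = []
    px_area = pixel_size_xy**2
    for z, res in enumerate(result.nuclei):
        for region in regionprops(res.labels.values):
            rows.append(
                {
                    "slice": z,
                    "label": int(region.label),
                    "centroid_row": float(region.centroid[0]),
                    "centroid_col": float(region.centroid[1]),
                    "area_um2": float(region.area) * px_area,
                }
            )
    return pd.DataFrame(
        rows, columns=["slice", "label", "centroid_row", "centroid_col", "area_um2"]
    )


def save_result(
    result: SegmentationResult,
    outdir: str | Path,
    config: RunConfig,
) -> dict:
    """Write all run artefacts into ``outdir``; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    voxel = (config.pixel_size_xy, config.pixel_size_xy, config.voxel_depth)

    write_mask_volume(result.membrane_masks, voxel, outdir / "membrane_masks.tif")
    write_label_volume(
        np.stack([m.values for m in result.membrane_labels]),
        voxel,
        outdir / "membrane_labels.tif",
    )
    write_label_volume(
        np.stack([r.labels.values for r in result.nuclei]),
        voxel,
        outdir / "nuclei_labels.tif",
    )
    if result.volume.membrane_volume.size:
        write_label_volume(
            result.volume.membrane_volume, voxel, outdir / "membrane_volume.tif"
        )
        write_label_volume(
            result.volume.nuclei_volume, voxel, outdir / "nuclei_volume.tif"
        )

    _nuclei_table(result, config.pixel_size_xy).to_csv(
        outdir / "nuclei.csv", index=False
    )
    cutoff_payload = {
        "cutoff_index": result.cutoff.cutoff_index,
        "triggered_rule": result.cutoff.triggered_rule,
        "per_slice": result.cutoff.per_slice_metrics,
    }
    (outdir / "cutoff.json").write_text(
        json.dumps(cutoff_payload, indent=2, sort_keys=True)
    )
    summary = {
        "n_slices": len(result.membrane_masks),
        "thresholds": result.thresholds,
        "nuclei_counts": result.nuclei_counts,
        "total_nuclei": int(sum(result.nuclei_counts)),
        "cutoff_index": result.cutoff.cutoff_index,
        "triggered_rule": result.cutoff.triggered_rule,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    # wall-clock log kept apart: every other artefact is deterministic
    (outdir / "timings.json").write_text(
        json.dumps({k: round(v, 3) for k, v in result.timings.items()}, sort_keys=True)
    )
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    return summary


def run_pipeline_path(
    input_path: str | Path, outdir: str | Path, config: RunConfig | None = None
) -> dict:
    """Read a stack from disk, run the pipeline, write all artefacts."""
    cfg = config or RunConfig()
    stack = read_stack(
        input_path,
        channel_map=cfg.channel_map,
        pixel_size_xy=cfg.pixel_size_xy,
        voxel_depth=cfg.voxel_depth,
        reverse=cfg.reverse_stack,
    )
    result = run_pipeline(stack, cfg)
    return save_result(result, outdir, cfg)


def run_eval(
    manual_dir: str | Path,
    auto_dir: str | Path,
    pixel_size_xy: float = 0.345,
    layer: str = "PHAL",
) -> pd.DataFrame:
    """Pairwise mask evaluation between two directories.

    Files are matched by name; unmatched files are reported and
    skipped. The returned frame has one row per pair plus an aggregate
    mean ± sd row, mirroring the usual reporting format for
    segmentation-agreement tables.
    """
    manual_dir, auto_dir = Path(manual_dir), Path(auto_dir)
    manual_files = {p.name: p for p in sorted(manual_dir.iterdir()) if p.is_file()}
    auto_files = {p.name: p for p in sorted(auto_dir.iterdir()) if p.is_file()}
    if not manual_files or not auto_files:
        raise FileNotFoundError("empty manual or automatic mask directory")
    common = sorted(manual_files.keys() & auto_files.keys())
    for name in sorted(manual_files.keys() ^ auto_files.keys()):
        logger.warning("unmatched mask file skipped: %s", name)
    if not common:
        raise FileNotFoundError("no matching mask filenames between directories")

    rows = []
    for name in common:
        manual = read_mask(manual_files[name], pixel_size_xy)
        auto = read_mask(auto_files[name], pixel_size_xy)
        rep = met.evaluate_masks(manual, auto)
        counts = met.confusion(manual, auto)
        rows.append(
            {
                "file": name,
                "layer": layer,
                "TP": counts.tp,
                "FP": counts.fp,
                "FN": counts.fn,
                "recall": rep.recall,
                "precision": rep.precision,
                "f1": rep.f1,
                "jaccard": rep.jaccard,
                "n_manual": rep.n_objects_manual,
                "n_auto": rep.n_objects_auto,
            }
        )
    df = pd.DataFrame(rows)
    agg = {"file": "mean±sd", "layer": layer}
    for col in ("recall", "precision", "f1", "jaccard"):
        agg[col] = df[col].mean()
        agg[f"{col}_sd"] = df[col].std(ddof=1) if len(df) > 1 else 0.0
    return pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
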