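"""Batch analysis: run a pipeline over images and tabulate results.

Thin orchestration over the two pipelines: reads images (plus optional
metadata sidecars), applies the shared rotation-alignment preprocessing,
runs the selected pipeline, and produces the per-cell table, per-image
summaries and per-donor profiles in the package's CSV/JSON schemas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import dog, sinewin
from .core import (
    Detection,
    FlowCondition,
    ImageSummary,
    IntensityGrid,
    PipelineConfig,
    estimate_rotation,
    read_image,
    read_metadata,
    rotate_align,
)
from .deformability import summarize_image

PIPELINES = {"sinewin": sinewin, "dog": dog}

CELL_COLUMNS = [
    "image",
    "donor_id",
    "group",
    "stress_dyn_cm2",
    "shear_rate_s1",
    "pipeline",
    "centroid_x",
    "centroid_y",
    "L_X",
    "L_Y",
    "orientation_deg",
    "DI",
    "accepted",
    "reject_reason",
]


def analyze_grid(
    grid: IntensityGrid,
    pipeline: str,
    config: PipelineConfig | None = None,
    align: str | float = "none",
) -> tuple[list[Detection], ImageSummary]:
    """Run one pipeline on a grid, optionally aligning streamlines first.

    ``align`` is ``"none"`` (grid already aligned), ``"auto"``
    (estimate the rotation from the streamline background) or an
    explicit angle in degrees.
    """
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}; choose from {sorted(PIPELINES)}")
    if align == "auto":
        grid = rotate_align(grid, estimate_rotation(grid))
    elif align != "none":
        grid = rotate_align(grid, float(align))
    detections = PIPELINES[pipeline].detect_and_measure(grid, config)
    accepted = [d for d in detections if d.accepted]
    summary = summarize_image(
        [_to_cell(d) for d in accepted], flow=None
    )
    return detections, summary


def _to_cell(d: Detection):
    from .core import CellMeasurement

    return CellMeasurement(
        L_X=d.L_X,
        L_Y=d.L_Y,
        centroid_x=d.centroid_x,
        centroid_y=d.centroid_y,
        orientation_deg=d.orientation_deg,
        DI=d.DI,
        pipeline_id=d.pipeline_id,
    )


def _sidecar(path: Path) -> dict:
    for suffix in (".yaml", ".yml"):
        side = path.with_suffix(suffix)
        if side.exists():
            return read_metadata(side)
    return {}


def analyze_images(
    paths: list[str | Path],
    pipeline: str,
    config: PipelineConfig | None = None,
    align: str | float = "none",
) -> tuple[pd.DataFrame, dict]:
    """Analyze image files; returns (per-cell table, per-image summaries).

    Each image may carry a YAML sidecar (same stem) with donor_id,
    group, stress_dyn_cm2, viscosity_mPas and calibration_um_per_px.
    """
    rows = []
    summaries: dict[str, dict] = {}
    for p in map(Path, paths):
        meta = _sidecar(p)
        grid = read_image(p, meta.get("calibration_um_per_px", 0.6))
        flow = None
        if "stress_dyn_cm2" in meta:
            flow = FlowCondition(
                meta["stress_dyn_cm2"], meta.get("viscosity_mPas", 1.12)
            )
        detections, summary = analyze_grid(grid, pipeline, config, align)
        summary.flow = flow
        summary.donor_id = meta.get("donor_id")
        summary.group_label = meta.get("group")
        for d in detections:
            rows.append(
                {
                    "image": p.name,
                    "donor_id": meta.get("donor_id"),
                    "group": meta.get("group"),
                    "stress_dyn_cm2": meta.get("stress_dyn_cm2"),
                    "shear_rate_s1": flow.rate_s1 if flow else None,
                    "pipeline": d.pipeline_id,
                    "centroid_x": d.centroid_x,
                    "centroid_y": d.centroid_y,
                    "L_X": d.L_X,
                    "L_Y": d.L_Y,
                    "orientation_deg": d.orientation_deg,
                    "DI": d.DI,
                    "accepted": d.accepted,
                    "reject_reason": d.reject_reason,
                }
            )
        summaries[p.name] = {
            "n_cells": summary.n_cells,
            "DI_Total": summary.DI_Total,
            "DI_Mean": summary.DI_Mean,
            "donor_id": summary.donor_id,
            "group": summary.group_label,
            "stress_dyn_cm2": meta.get("stress_dyn_cm2"),
            "shear_rate_s1": flow.rate_s1 if flow else None,
        }
    table = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return table, summaries


def write_results(
    out_dir: str | Path, cells: pd.DataFrame, summaries: dict
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells_path = out / "cells.csv"
    summary_path = out / "summaries.json"
    cells.to_csv(cells_path, index=False)
    with open(summary_path, "w") as fh:
        json.dump(summaries, fh, indent=2)
    return cells_path, summary_path


def donor_profile_table(summaries: list[ImageSummary]) -> pd.DataFrame:
    """Donor profile CSV schema from per-image summaries of one donor."""
    from .deformability import aggregate_donor

    profile = aggregate_donor(summaries)
    return pd.DataFrame(
        {
            "donor_id": profile.donor_id,
            "group": profile.group_label,
            "shear_rate_s1": profile.rates_s1,
            "n_cells": profile.n_cells,
            "di_mean": profile.di_means,
        }
    )
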