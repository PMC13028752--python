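"""Deformability index, per-image and per-donor aggregation, shear conversion.

The deformability index of a single cell is

    DI = (L_X - L_Y) / (L_X + L_Y)

where L_X is the extent along the flow axis and L_Y the transverse
extent.  DI is 0 for a circle and approaches 1 for extreme elongation,
and is invariant to uniform rescaling of the cell.  Within one image the
accepted-cell DIs are summed (DI_Total) and averaged (DI_Mean); per
donor, cell DIs are pooled across the images taken at one shear
condition.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Sequence

from .core import CellMeasurement, DonorProfile, FlowCondition, ImageSummary

__all__ = [
    "deformability_index",
    "summarize_image",
    "aggregate_donor",
    "stress_to_rate",
    "format_rate",
]


def deformability_index(L_X: float, L_Y: float) -> float:
    """(L_X − L_Y)/(L_X + L_Y); negative if L_Y > L_X (caller orients axes)."""
    if not (L_X > 0 and L_Y > 0):
        raise ValueError("cell extents must be positive")
    return (L_X - L_Y) / (L_X + L_Y)


def summarize_image(
    cells: Sequence[CellMeasurement],
    flow: FlowCondition | None = None,
    donor_id: str | None = None,
    group_label: str | None = None,
) -> ImageSummary:
    """Sum and average the DI of an image's accepted cells.

    An image with no accepted cells has DI_Total 0 and DI_Mean None.
    """
    total = sum(c.DI for c in cells)
    n = len(cells)
    mean = total / n if n > 0 else None
    return ImageSummary(
        n_cells=n,
        DI_Total=total,
        DI_Mean=mean,
        flow=flow,
        donor_id=donor_id,
        group_label=group_label,
    )


def aggregate_donor(
    summaries: Sequence[ImageSummary],
    min_images: int = 5,
    weighting: str = "cell",
) -> DonorProfile:
    """Pool a donor's image summaries into a per-shear-rate DI profile.

    ``weighting="cell"`` (default) pools all accepted-cell DI values of a
    condition's images, i.e. weights images by cell count;
    ``weighting="image"`` averages the per-image means instead.  A
    warning is emitted for conditions imaged fewer than ``min_images``
    times.
    """
    if weighting not in ("cell", "image"):
        raise ValueError("weighting must be 'cell' or 'image'")
    if not summaries:
        raise ValueError("no image summaries supplied")
    donor_ids = {s.donor_id for s in summaries}
    if len(donor_ids) != 1:
        raise ValueError(f"summaries mix donor ids: {sorted(map(str, donor_ids))}")
    groups = {s.group_label for s in summaries}

    by_rate: dict[float, list[ImageSummary]] = defaultdict(list)
    for s in summaries:
        if s.flow is None:
            raise ValueError("each summary needs a flow condition")
        by_rate[s.flow.rate_s1].append(s)

    rates, means, counts = [], [], []
    for rate in sorted(by_rate):
        images = by_rate[rate]
        if len(images) < min_images:
            warnings.warn(
                f"shear rate {rate:g} s^-1 has only {len(images)} image(s); "
                f"at least {min_images} are recommended",
                stacklevel=2,
            )
        n_cells = sum(s.n_cells for s in images)
        if weighting == "cell":
            total = sum(s.DI_Total for s in images)
            mean = total / n_cells if n_cells > 0 else None
        else:
            with_cells = [s.DI_Mean for s in images if s.n_cells > 0]
            mean = sum(with_cells) / len(with_cells) if with_cells else None
        rates.append(rate)
        means.append(mean)
        counts.append(n_cells)

    return DonorProfile(
        donor_id=next(iter(donor_ids)),
        group_label=next(iter(groups)) if len(groups) == 1 else None,
        rates_s1=rates,
        di_means=means,
        n_cells=counts,
    )


def stress_to_rate(stress_dyn_cm2: float, viscosity_mPas: float) -> float:
    """Newtonian wall shear rate γ̇ = τ/μ in s⁻¹.

    τ in dyn/cm² (= 0.1 Pa) and μ in mPa·s (= 1e-3 Pa·s) give
    γ̇ = 100·τ/μ.
    """
    if not (stress_dyn_cm2 > 0 and viscosity_mPas > 0):
        raise ValueError("stress and viscosity must be positive")
    return 100.0 * stress_dyn_cm2 / viscosity_mPas


def format_rate(rate_s1: float) -> str:
    """Report a shear rate: nearest integer, one decimal below 10 s⁻¹."""
    if rate_s1 < 10:
        return f"{rate_s1:.1f}"
    return f"{rate_s1:.0f}"
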