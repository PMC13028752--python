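"""Difference-of-Gaussians pipeline (the Python-style workflow).

A band-pass filter — the difference of a narrow (σ₁ = 0.7 px) and a wide
(σ₂ = 16 px) Gaussian smoothing — suppresses the slowly varying
streamline background and leaves cells as bright compact regions.  A
white top-hat with a horizontal line element (45 px) then removes
elongated horizontal flow streaks, and the result is binarized at an
Otsu threshold scaled by 1.06.  Components touching the image border are
discarded, components with 50–130 px of area are kept, and each kept
component is measured by its farthest pixel pair: the maximal-distance
axis defines L_X and the orientation, the perpendicular projection
extent defines L_Y.  Cells with DI > 0.35 are rejected as artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core import (
    CellMeasurement,
    Detection,
    FlowCondition,
    ImageSummary,
    IntensityGrid,
    PipelineConfig,
)
from .deformability import deformability_index, summarize_image

__all__ = [
    "LabeledComponents",
    "dog_filter",
    "tophat_horizontal",
    "otsu_threshold",
    "segment",
    "principal_axes",
    "run_dog",
]

PIPELINE_ID = "dog"


@dataclass
class LabeledComponents:
    """Retained 8-connected components of a segmented image."""

    labels: np.ndarray
    pixel_sets: dict[int, np.ndarray] = field(default_factory=dict)
    areas: dict[int, int] = field(default_factory=dict)
    removed: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, pixels in self.pixel_sets.items():
            if label <= 0:
                raise ValueError("labels must be positive integers")
            if self.areas.get(label) != pixels.shape[0]:
                raise ValueError("area must equal the pixel-set size")


def dog_filter(
    grid: IntensityGrid, sigma1: float = 0.7, sigma2: float = 16.0
) -> IntensityGrid:
    """Band-pass: G(σ₁)∗image − G(σ₂)∗image, edge-replicated boundaries."""
    if not 0 < sigma1 < sigma2:
        raise ValueError("require 0 < sigma1 < sigma2")
    narrow = ndimage.gaussian_filter(grid.values, sigma1, mode="nearest")
    wide = ndimage.gaussian_filter(grid.values, sigma2, mode="nearest")
    return grid.with_values(narrow - wide)


def tophat_horizontal(grid: IntensityGrid, length_px: int = 45) -> IntensityGrid:
    """White top-hat with a 1×length horizontal line element.

    Structures that can contain the horizontal element (e.g. flow
    streaks longer than it) survive the opening and are removed from the
    output; compact objects narrower than the element are preserved.
    Even lengths are promoted to the next odd number (with a warning)
    so the element is symmetric.  Output is in [0, input] everywhere.
    """
    if length_px < 1:
        raise ValueError("structuring element length must be >= 1")
    if length_px % 2 == 0:
        warnings.warn(
            f"even structuring element length {length_px} promoted to "
            f"{length_px + 1}",
            stacklevel=2,
        )
        length_px += 1
    opened = ndimage.grey_opening(
        grid.values, footprint=np.ones((1, length_px), dtype=bool), mode="nearest"
    )
    return grid.with_values(grid.values - opened)


def otsu_threshold(grid: IntensityGrid | np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a histogram over the observed value range.

    The classic 8-bit formulation does not apply directly to the
    real-valued band-pass output, so the histogram uses ``nbins`` equal
    bins spanning [min, max].  Returns the bin centre maximizing the
    between-class variance ω₀ω₁(μ₀ − μ₁)²; ties break toward the
    smallest threshold.  A constant image is an error.
    """
    values = grid.values if isinstance(grid, IntensityGrid) else np.asarray(grid)
    values = values.ravel().astype(float)
    if values.size == 0 or np.ptp(values) == 0:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    mass = np.cumsum(counts * centers)
    # class means for split "<= bin k" vs "> bin k"
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mass / w0
        mu1 = (mass[-1] - mass) / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
    score[~np.isfinite(score)] = -np.inf
    score = score[:-1]
    # near-ties (within 1e-10 relative) break toward the smallest threshold,
    # so the choice is stable against summation-order rounding
    top = score.max()
    best = int(np.flatnonzero(score >= top - 1e-10 * abs(top))[0])
    return float(centers[best])


def segment(
    grid: IntensityGrid, config: PipelineConfig | None = None
) -> LabeledComponents:
    """Binarize at otsu × ``otsu_factor`` and filter components.

    Foreground is ``value >= scaled threshold``; components are labeled
    with 8-connectivity.  Components touching any image border are
    removed, then only components with area inside ``area_range_px``
    (inclusive) are retained.  Removed labels are recorded with the
    reason (``"border"`` or ``"area"``).
    """
    config = config or PipelineConfig()
    thr = otsu_threshold(grid) * config.otsu_factor
    binary = grid.values >= thr
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    h, w = labels.shape
    lo, hi = config.area_range_px
    out = LabeledComponents(labels=labels.copy())
    for label, idx in ndimage.value_indices(labels, ignore_value=0).items():
        rows, cols = idx
        touches = (
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == h - 1
            or cols.max() == w - 1
        )
        area = rows.size
        if touches:
            out.removed[int(label)] = "border"
        elif not lo <= area <= hi:
            out.removed[int(label)] = "area"
        else:
            out.pixel_sets[int(label)] = np.column_stack(idx)
            out.areas[int(label)] = int(area)
        if int(label) in out.removed:
            out.labels[idx] = 0
    return out


def principal_axes(pixels: np.ndarray) -> tuple[float, float, float]:
    """Farthest-pair axis measurement of a pixel set.

    The pixel-centre pair at maximal Euclidean distance (searched over
    the convex hull; ties broken by lexicographic (row, col) pixel
    order) defines the primary axis: L_X is that distance + 1 and the
    orientation is the axis angle in degrees.  All pixel centres are
    projected on the axis's perpendicular, and L_Y is the projection
    extent + 1.  The +1 pixel-extent convention makes a single-file row
    of k pixels measure length k.
    """
    pts = np.asarray(pixels)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (N>=2, 2) array of (row, col) pixels")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order].astype(float)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear pixel sets have no 2-D hull
        hull = pts
    diff = hull[:, None, :] - hull[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    dmax = dist.max()
    # lexicographically smallest maximal pair (pts are sorted)
    i, j = np.argwhere(np.isclose(dist, dmax))[0]
    p, q = hull[i], hull[j]
    if tuple(q) < tuple(p):
        p, q = q, p
    L_X = dmax + 1.0
    axis = (q - p) / dmax  # (drow, dcol)
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    L_Y = float(np.ptp(proj)) + 1.0
    orientation = np.degrees(np.arctan2(axis[0], axis[1]))
    orientation = (orientation + 90.0) % 180.0 - 90.0
    if orientation == -90.0:
        orientation = 90.0
    return float(L_X), L_Y, float(orientation)


def detect_and_measure(
    grid: IntensityGrid, config: PipelineConfig | None = None
) -> list[Detection]:
    """Full DoG measurement chain, keeping DI-capped rejects."""
    config = config or PipelineConfig()
    filtered = dog_filter(grid, config.dog_sigma1, config.dog_sigma2)
    hat = tophat_horizontal(filtered, config.tophat_length_px)
    try:
        components = segment(hat, config)
    except ValueError:
        return []
    detections: list[Detection] = []
    for label in sorted(components.pixel_sets):
        pixels = components.pixel_sets[label]
        L_X, L_Y, orientation = principal_axes(pixels)
        if L_Y > L_X:  # degenerate non-convex shape; not a deformed cell
            continue
        di = deformability_index(L_X, L_Y)
        accepted = di <= config.di_cap
        detections.append(
            Detection(
                L_X=L_X,
                L_Y=L_Y,
                centroid_x=float(pixels[:, 1].mean()),
                centroid_y=float(pixels[:, 0].mean()),
                orientation_deg=orientation,
                DI=di,
                accepted=accepted,
                reject_reason=None if accepted else "di_cap",
                pipeline_id=PIPELINE_ID,
            )
        )
    return detections


def run_dog(
    grid: IntensityGrid,
    config: PipelineConfig | None = None,
    flow: FlowCondition | None = None,
    donor_id: str | None = None,
    group_label: str | None = None,
) -> tuple[list[CellMeasurement], ImageSummary]:
    """Run the DoG pipeline on a monochrome, rotation-aligned grid."""
    detections = detect_and_measure(grid, config)
    cells = [
        CellMeasurement(
            L_X=d.L_X,
            L_Y=d.L_Y,
            centroid_x=d.centroid_x,
            centroid_y=d.centroid_y,
            orientation_deg=d.orientation_deg,
            DI=d.DI,
            pipeline_id=PIPELINE_ID,
        )
        for d in detections
        if d.accepted
    ]
    summary = summarize_image(cells, flow, donor_id, group_label)
    return cells, summary
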