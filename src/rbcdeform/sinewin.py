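"""Sine-window convolution pipeline (the LabVIEW-style workflow).

The streamline background of a microfluidic brightfield image varies
smoothly along the flow (X) axis.  Convolving each row with a normalized
squared half-cycle sine window blurs the background while smearing out
the small cells; subtracting the blurred image from the original leaves
the cells as localized bright residuals.  The residual is contrast
stretched, Gaussian smoothed, Otsu binarized, and each detected object
is measured by fitting an ellipse to its contour with a direct
least-squares conic fit.  A cell is accepted only if

  (a) L_X > L_Y,
  (b) L_X − L_Y ≥ 0.2·L_X, and
  (c) L_X and L_Y fall inside the configured size windows
      (default 4 ≤ L_X ≤ 9 and 2.5 ≤ L_Y ≤ 7),

where L_X and L_Y are the fitted major and minor ellipse diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours

from .core import (
    CellMeasurement,
    Detection,
    FlowCondition,
    ImageSummary,
    IntensityGrid,
    PipelineConfig,
)
from .deformability import deformability_index, summarize_image
from .dog import otsu_threshold

__all__ = [
    "Kernel",
    "EllipseParams",
    "sine_window_kernel",
    "suppress_background",
    "enhance",
    "detect_objects",
    "fit_ellipse",
    "accept_cell",
    "run_sinewin",
]

PIPELINE_ID = "sinewin"


@dataclass(frozen=True)
class Kernel:
    """1-D convolution kernel: non-negative weights summing to one,
    symmetric about the centre with the maximum at the centre."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("kernel must be a non-empty 1-D array")
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to one")

    @property
    def length(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class EllipseParams:
    """Fitted ellipse: centre, diameters (major >= minor), orientation."""

    center_x: float
    center_y: float
    major_diameter: float
    minor_diameter: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not (self.major_diameter >= self.minor_diameter > 0):
            raise ValueError("require major_diameter >= minor_diameter > 0")


def sine_window_kernel(n: int) -> Kernel:
    """Normalized squared half-cycle sine window with ``n`` samples.

    Midpoint sampling, w_k ∝ sin²(π(k + ½)/n), avoids the zero-valued
    endpoints of the endpoint convention and behaves sensibly down to
    n = 1 (a single sample normalizes to [1]).
    """
    if n < 1:
        raise ValueError("kernel length must be >= 1")
    k = np.arange(n, dtype=float)
    w = np.sin(np.pi * (k + 0.5) / n) ** 2
    return Kernel(w / w.sum())


def suppress_background(grid: IntensityGrid, kernel: Kernel) -> IntensityGrid:
    """Row-wise background subtraction: original − (row ∗ kernel).

    Rows are convolved with edge-replicated boundaries at the original
    width.  An even-length kernel has no centre sample, so it is centred
    by averaging its two half-sample alignments (equivalent to an
    odd-length kernel of the same mass); this keeps the operator exactly
    symmetric, so constants map to zero everywhere and linear ramps map
    to zero away from the edges.  The residual may be negative.
    """
    w = kernel.weights
    if kernel.length > grid.width:
        raise ValueError(
            f"kernel length {kernel.length} exceeds image width {grid.width}"
        )
    if kernel.length % 2 == 0:
        w = np.convolve(w, [0.5, 0.5])
    filtered = ndimage.convolve1d(grid.values, w, axis=1, mode="nearest")
    return grid.with_values(grid.values - filtered)


def enhance(
    grid: IntensityGrid,
    contrast_percentiles: tuple[float, float] = (50.0, 99.9),
    gaussian_sigma: float = 1.0,
) -> IntensityGrid:
    """Percentile contrast stretch to [0, 255] plus Gaussian smoothing.

    The p_low/p_high percentiles of the residual map to 0/255 with
    clipping; a degenerate percentile range (equal percentile values)
    yields a zero grid with a warning.  The default (50, 99.9) window
    pins the background median to 0 — clipping the negative residual, in
    keeping with cells being bright — and keeps the background residual
    narrow, so that Otsu binarization separates cells from background
    rather than splitting background structure.
    """
    p_low, p_high = contrast_percentiles
    if not (0 <= p_low < p_high <= 100):
        raise ValueError("require 0 <= p_low < p_high <= 100")
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    lo, hi = np.percentile(grid.values, [p_low, p_high])
    if hi == lo:
        warnings.warn(
            "degenerate contrast percentiles (flat residual); returning zeros",
            stacklevel=2,
        )
        return grid.with_values(np.zeros_like(grid.values))
    out = np.clip((grid.values - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, gaussian_sigma, mode="nearest")
    return grid.with_values(out)


def detect_objects(
    grid: IntensityGrid,
    diameter_range_px: tuple[float, float] = (3.0, 50.0),
) -> list[np.ndarray]:
    """Otsu-binarize the enhanced residual and keep round-sized blobs.

    8-connected components whose equivalent-circle diameter 2·√(area/π)
    lies in ``diameter_range_px`` are returned as (row, col) pixel-index
    arrays.
    """
    try:
        thr = otsu_threshold(grid)
    except ValueError:
        return []
    binary = grid.values >= thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    kept: list[np.ndarray] = []
    lo, hi = diameter_range_px
    for idx in ndimage.value_indices(labels, ignore_value=0).values():
        area = idx[0].size
        diameter = 2.0 * np.sqrt(area / np.pi)
        if lo <= diameter <= hi:
            kept.append(np.column_stack(idx))
    return kept


def _moment_ellipse(pixels: np.ndarray) -> EllipseParams:
    """Ellipse with the same centroid and second central moments as the
    pixel set (semi-axis = 2·√eigenvalue of the coordinate covariance)."""
    ys = pixels[:, 0].astype(float)
    xs = pixels[:, 1].astype(float)
    cx, cy = xs.mean(), ys.mean()
    cov = np.cov(np.vstack([xs, ys]), bias=True)
    if pixels.shape[0] < 3 or np.linalg.matrix_rank(cov) < 2:
        raise ValueError("need >= 3 non-collinear pixels for a moment ellipse")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    major = 4.0 * np.sqrt(evals[0])
    minor = 4.0 * np.sqrt(evals[1])
    angle = np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return EllipseParams(cx, cy, major, minor, _normalize_angle(angle))


def _normalize_angle(angle_deg: float) -> float:
    """Fold an axis orientation into (−90, 90]."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def fit_ellipse(points: np.ndarray, pixel_set: bool | None = None) -> EllipseParams:
    """Least-squares ellipse through contour points, moment fallback.

    ``points`` is either an (N, 2) array of subpixel contour points in
    (x, y) order (``pixel_set=False``) or an (N, 2) array of integer
    (row, col) pixel indices (``pixel_set=True``; inferred from dtype if
    omitted).  Contours with at least 5 distinct points get a direct
    least-squares conic fit; a degenerate or non-elliptical fit falls
    back to the second-order moment ellipse of the same points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (N, 2) point array")
    if pixel_set is None:
        pixel_set = np.issubdtype(np.asarray(points).dtype, np.integer)
    if pixel_set:
        if pts.shape[0] < 3:
            raise ValueError("need >= 3 pixels")
        return _moment_ellipse(np.asarray(points))
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 3:
        raise ValueError("need >= 3 distinct points")
    if distinct.shape[0] >= 5:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = EllipseModel.from_estimate(pts)
        if model:
            ax0, ax1 = model.axis_lengths
            theta = np.degrees(model.theta)
            if ax1 > ax0:
                ax0, ax1 = ax1, ax0
                theta += 90.0
            if ax1 > 1e-9 and np.isfinite([ax0, ax1, theta]).all():
                return EllipseParams(
                    float(model.center[0]),
                    float(model.center[1]),
                    2.0 * float(ax0),
                    2.0 * float(ax1),
                    _normalize_angle(theta),
                )
    # moment fallback on the point cloud itself: a uniform contour has the
    # covariance structure of the ellipse outline, whose eigenvectors give
    # the axes; rescale from outline to filled-region convention.
    rc = np.column_stack([pts[:, 1], pts[:, 0]])
    cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 0:
        raise ValueError("degenerate point configuration")
    # outline second moments of an ellipse are ~a²/2; use √2 scaling
    major = 2.0 * np.sqrt(2.0 * evals[0])
    minor = 2.0 * np.sqrt(2.0 * evals[1])
    angle = np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return EllipseParams(cx, cy, major, minor, _normalize_angle(angle))


def accept_cell(
    L_X: float,
    L_Y: float,
    config: PipelineConfig,
    calibration_um_per_px: float = 0.6,
) -> tuple[bool, str | None]:
    """Apply the three geometric acceptance criteria.

    Returns ``(accepted, reason)`` where ``reason`` names the first
    failed criterion (``"a"``, ``"b"`` or ``"c"``) or is None.  With
    ``criteria_units="micrometers"`` the size windows of criterion (c)
    are compared against extents converted with the calibration.
    """
    if not (L_X > 0 and L_Y > 0):
        raise ValueError("extents must be positive")
    if not L_X > L_Y:
        return False, "a"
    if not (L_X - L_Y) >= config.elongation_fraction * L_X:
        return False, "b"
    scale = calibration_um_per_px if config.criteria_units == "micrometers" else 1.0
    lx, ly = L_X * scale, L_Y * scale
    if not (config.lx_range[0] <= lx <= config.lx_range[1]):
        return False, "c"
    if not (config.ly_range[0] <= ly <= config.ly_range[1]):
        return False, "c"
    return True, None


def _component_contour(
    enhanced: np.ndarray, pixels: np.ndarray, labels: np.ndarray
) -> np.ndarray | None:
    """Subpixel outer contour of one detected component.

    The boundary is localized at the component's half-amplitude
    (mid-reference) level — midway between its interior plateau and the
    local background — rather than at the global binarization threshold,
    which sits in the blur skirt of saturated objects and would bias the
    fitted diameters.  ``enhanced`` should be the *unclipped* smoothed
    residual so the local background (including the negative trough the
    kernel subtraction leaves beside a cell) is measurable.  The image
    is cropped around the component with other components suppressed,
    and the longest iso-contour at the mid level is returned in (x, y)
    order.
    """
    rmin, cmin = pixels.min(axis=0)
    rmax, cmax = pixels.max(axis=0)
    pad = 6
    r0, c0 = max(rmin - pad, 0), max(cmin - pad, 0)
    r1 = min(rmax + pad + 1, enhanced.shape[0])
    c1 = min(cmax + pad + 1, enhanced.shape[1])
    crop = enhanced[r0:r1, c0:c1].copy()
    lab_crop = labels[r0:r1, c0:c1]
    this_label = labels[pixels[0, 0], pixels[0, 1]]
    other = (lab_crop > 0) & (lab_crop != this_label)
    # The row-wise kernel subtraction depresses the background of the
    # rows a cell occupies (it subtracts the cell's own smeared mass),
    # so each crop row's baseline is read from side strips outside the
    # component and removed; the half-plateau level of the flattened
    # profile then localizes the half-amplitude edge on every side.
    strip = np.ones_like(lab_crop, dtype=bool)
    strip[:, max(cmin - c0 - 1, 0) : cmax - c0 + 2] = False
    strip &= lab_crop == 0
    baseline = np.zeros(crop.shape[0])
    overall = np.median(crop[lab_crop == 0]) if (lab_crop == 0).any() else 0.0
    for row in range(crop.shape[0]):
        vals = crop[row, strip[row]]
        baseline[row] = np.median(vals) if vals.size >= 3 else overall
    flat = crop - baseline[:, None]
    interior = np.percentile(flat[lab_crop == this_label], 90)
    if interior <= 0:
        return None
    mid = 0.5 * interior
    flat[other] = min(flat.min(), mid - 1.0)
    contours = find_contours(flat, mid)
    if not contours:
        return None
    contour = max(contours, key=len)
    return np.column_stack([contour[:, 1] + c0, contour[:, 0] + r0])


def detect_and_measure(
    grid: IntensityGrid, config: PipelineConfig | None = None
) -> list[Detection]:
    """Full sine-window measurement chain, keeping rejected objects."""
    config = config or PipelineConfig()
    kernel = sine_window_kernel(config.kernel_length)
    residual = suppress_background(grid, kernel)
    enhanced = enhance(
        residual, config.contrast_percentiles, config.gaussian_sigma_sinewin
    )
    if np.ptp(enhanced.values) == 0:
        return []
    # unclipped smoothed residual for subpixel boundary localization
    smoothed = (
        ndimage.gaussian_filter(residual.values, config.gaussian_sigma_sinewin,
                                mode="nearest")
        if config.gaussian_sigma_sinewin > 0
        else residual.values
    )
    thr = otsu_threshold(enhanced)
    binary = enhanced.values >= thr
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    detections: list[Detection] = []
    lo, hi = config.diameter_range_px
    for idx in ndimage.value_indices(labels, ignore_value=0).values():
        pixels = np.column_stack(idx)
        area = pixels.shape[0]
        if not lo <= 2.0 * np.sqrt(area / np.pi) <= hi:
            continue
        contour = _component_contour(smoothed, pixels, labels)
        try:
            if contour is not None and contour.shape[0] >= 5:
                params = fit_ellipse(contour, pixel_set=False)
            else:
                params = fit_ellipse(pixels, pixel_set=True)
        except ValueError:
            continue
        accepted, reason = accept_cell(
            params.major_diameter,
            params.minor_diameter,
            config,
            grid.calibration_um_per_px,
        )
        detections.append(
            Detection(
                L_X=params.major_diameter,
                L_Y=params.minor_diameter,
                centroid_x=params.center_x,
                centroid_y=params.center_y,
                orientation_deg=params.orientation_deg,
                DI=deformability_index(params.major_diameter, params.minor_diameter),
                accepted=accepted,
                reject_reason=reason,
                pipeline_id=PIPELINE_ID,
            )
        )
    return detections


def run_sinewin(
    grid: IntensityGrid,
    config: PipelineConfig | None = None,
    flow: FlowCondition | None = None,
    donor_id: str | None = None,
    group_label: str | None = None,
) -> tuple[list[CellMeasurement], ImageSummary]:
    """Run the sine-window pipeline on a monochrome, rotation-aligned grid."""
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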