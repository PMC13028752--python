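"""Shared data model and image-level primitives.

Images of red blood cells flowing through a microfluidic channel are
represented as :class:`IntensityGrid` objects: a 2-D array of real-valued
pixel intensities plus a spatial calibration (micrometres per pixel).
This module also carries the small record types used throughout the
package — per-cell measurements, per-image summaries, per-donor shear
profiles, the flow condition, and the pipeline configuration — and the
preprocessing steps both analysis pipelines share: monochrome conversion
and rotation that aligns the flow streamlines with the image X axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "IntensityGrid",
    "FlowCondition",
    "CellMeasurement",
    "Detection",
    "ImageSummary",
    "DonorProfile",
    "PipelineConfig",
    "to_monochrome",
    "rotate_align",
    "estimate_rotation",
    "read_image",
    "write_image",
    "read_metadata",
    "write_metadata",
]

#: Default spatial calibration of the imaging system, micrometres per pixel.
DEFAULT_UM_PER_PX = 0.6

#: Default suspension viscosity (mPa·s) of red cells diluted in dextran.
DEFAULT_VISCOSITY_MPAS = 1.12


@dataclass
class IntensityGrid:
    """A 2-D raster of pixel intensities with spatial calibration.

    Intensities are carried as floating point numbers internally; 8-bit
    inputs map onto [0, 255].  Quantisation back to 8 bits happens only
    on export (:func:`write_image`).
    """

    values: np.ndarray
    calibration_um_per_px: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pixel intensities must be finite")
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration_um_per_px must be positive")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "IntensityGrid":
        """New grid with the same calibration but different pixel data."""
        return IntensityGrid(values, self.calibration_um_per_px)


@dataclass(frozen=True)
class FlowCondition:
    """Wall shear stress τ (dyn/cm²), suspension viscosity μ (mPa·s) and
    the resulting Newtonian wall shear rate γ̇ = τ/μ (s⁻¹)."""

    stress_dyn_cm2: float
    viscosity_mPas: float = DEFAULT_VISCOSITY_MPAS
    rate_s1: float | None = None

    def __post_init__(self) -> None:
        if not self.stress_dyn_cm2 > 0:
            raise ValueError("shear stress must be positive")
        if not self.viscosity_mPas > 0:
            raise ValueError("viscosity must be positive")
        if self.rate_s1 is None:
            # γ̇ = τ/μ with dyn/cm² → 0.1 Pa and mPa·s → 1e-3 Pa·s
            object.__setattr__(
                self, "rate_s1", 100.0 * self.stress_dyn_cm2 / self.viscosity_mPas
            )
        if not self.rate_s1 > 0:
            raise ValueError("shear rate must be positive")


@dataclass(frozen=True)
class CellMeasurement:
    """One accepted cell: extents along the flow axis (L_X) and transverse
    to it (L_Y), centroid, orientation, and deformability index
    DI = (L_X − L_Y)/(L_X + L_Y)."""

    L_X: float
    L_Y: float
    centroid_x: float
    centroid_y: float
    orientation_deg: float
    DI: float
    pipeline_id: str

    def __post_init__(self) -> None:
        if not (self.L_X >= self.L_Y > 0):
            raise ValueError("accepted cells require L_X >= L_Y > 0")
        if not (0 <= self.DI < 1):
            raise ValueError("DI of an accepted cell lies in [0, 1)")
        expected = (self.L_X - self.L_Y) / (self.L_X + self.L_Y)
        if abs(self.DI - expected) > 1e-9:
            raise ValueError("DI inconsistent with (L_X - L_Y)/(L_X + L_Y)")


@dataclass
class Detection:
    """One measured object, accepted or not (produced by both pipelines)."""

    L_X: float
    L_Y: float
    centroid_x: float
    centroid_y: float
    orientation_deg: float
    DI: float
    accepted: bool
    reject_reason: str | None
    pipeline_id: str


@dataclass
class ImageSummary:
    """Accepted-cell count plus DI_Total (sum) and DI_Mean for one image."""

    n_cells: int
    DI_Total: float
    DI_Mean: float | None
    flow: FlowCondition | None = None
    donor_id: str | None = None
    group_label: str | None = None


@dataclass
class DonorProfile:
    """Per-donor mean DI at each applied shear condition (nominally 7)."""

    donor_id: str
    group_label: str | None
    rates_s1: list[float]
    di_means: list[float]
    n_cells: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.rates_s1) != sorted(self.rates_s1) or len(
            set(self.rates_s1)
        ) != len(self.rates_s1):
            raise ValueError("shear rates must be strictly increasing")
        for d in self.di_means:
            if d is not None and not (0 <= d < 1):
                raise ValueError("DI_Mean must lie in [0, 1)")


@dataclass
class PipelineConfig:
    """Tunable parameters of both analysis pipelines.

    Geometric acceptance bounds (``lx_range``, ``ly_range``) are
    interpreted in ``criteria_units``: ``"pixels"`` applies them to raw
    pixel extents, ``"micrometers"`` converts extents with the grid
    calibration first.  The pixel reading of the published 4–9 / 2.5–7
    bounds is smaller than an elongated red cell at 0.6 µm/px, so the
    micrometre switch is provided for physically scaled data.
    """

    # sine-window (LabVIEW-style) pipeline
    kernel_length: int = 100
    gaussian_sigma_sinewin: float = 1.0
    contrast_percentiles: tuple[float, float] = (50.0, 99.9)
    diameter_range_px: tuple[float, float] = (3.0, 50.0)
    lx_range: tuple[float, float] = (4.0, 9.0)
    ly_range: tuple[float, float] = (2.5, 7.0)
    elongation_fraction: float = 0.2
    criteria_units: str = "pixels"
    # difference-of-Gaussians (Python-style) pipeline
    dog_sigma1: float = 0.7
    dog_sigma2: float = 16.0
    tophat_length_px: int = 45
    otsu_factor: float = 1.06
    area_range_px: tuple[float, float] = (50.0, 130.0)
    di_cap: float = 0.35

    def __post_init__(self) -> None:
        for name in ("contrast_percentiles", "diameter_range_px", "lx_range",
                     "ly_range", "area_range_px"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        if self.kernel_length < 1:
            raise ValueError("kernel_length must be >= 1")
        for name in ("gaussian_sigma_sinewin", "dog_sigma1", "dog_sigma2"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.dog_sigma1 < self.dog_sigma2:
            raise ValueError("require 0 < dog_sigma1 < dog_sigma2")
        if self.criteria_units not in ("pixels", "micrometers"):
            raise ValueError("criteria_units must be 'pixels' or 'micrometers'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def replace(self, **changes) -> "PipelineConfig":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# preprocessing


def to_monochrome(
    image: np.ndarray, calibration_um_per_px: float = DEFAULT_UM_PER_PX
) -> IntensityGrid:
    """Convert a 1- or 3-channel raster to a single-channel grid.

    The microscope stores nominally monochrome frames as RGB with equal
    channels, so channel 0 is taken verbatim; if channels disagree
    anywhere by more than one intensity unit a warning is emitted.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("zero-sized image")
    if arr.ndim == 2:
        return IntensityGrid(arr, calibration_um_per_px)
    if arr.ndim == 3 and arr.shape[2] == 3:
        spread = np.max(arr, axis=2) - np.min(arr, axis=2)
        if np.any(spread > 1.0):
            warnings.warn(
                "RGB channels differ by more than 1 intensity unit; "
                "using channel 0",
                stacklevel=2,
            )
        return IntensityGrid(arr[:, :, 0], calibration_um_per_px)
    raise ValueError(f"expected 1 or 3 channels, got array of shape {arr.shape}")


def rotate_align(grid: IntensityGrid, angle_deg: float) -> IntensityGrid:
    """Rotate the grid by ``angle_deg`` about its centre.

    Bilinear interpolation, same output dimensions, out-of-frame pixels
    filled by edge replication so no dark frame survives background
    subtraction as a false object.  Angle 0 is the identity.
    """
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if angle_deg == 0.0:
        return grid.with_values(grid.values.copy())
    out = ndimage.rotate(
        grid.values, angle_deg, reshape=False, order=1, mode="nearest"
    )
    return grid.with_values(out)


def estimate_rotation(
    grid: IntensityGrid,
    search_range_deg: float = 10.0,
    step_deg: float = 0.1,
) -> float:
    """Estimate the angle that aligns the streamlines horizontally.

    The streamline background varies smoothly along X and sharply along
    Y, so when it is horizontal the variance of row means is maximal.
    A deterministic grid search over ``[-search_range_deg,
    +search_range_deg]`` returns the maximising angle, ties broken
    toward the smallest ``|angle|``.  A constant grid yields 0 with a
    warning.
    """
    if not step_deg > 0:
        raise ValueError("step_deg must be positive")
    if not search_range_deg >= 0:
        raise ValueError("search_range_deg must be non-negative")
    if np.ptp(grid.values) == 0:
        warnings.warn("constant image: rotation angle is undefined, returning 0",
                      stacklevel=2)
        return 0.0
    n = int(round(search_range_deg / step_deg))
    candidates = sorted(
        (step_deg * k for k in range(-n, n + 1)), key=lambda a: (abs(a), a)
    )
    best_angle, best_score = 0.0, -np.inf
    for angle in candidates:
        rotated = rotate_align(grid, angle)
        score = float(np.var(rotated.values.mean(axis=1)))
        if score > best_score:
            best_angle, best_score = angle, score
    return best_angle


# ---------------------------------------------------------------------------
# file I/O


def read_image(path: str | Path, calibration_um_per_px: float = DEFAULT_UM_PER_PX
               ) -> IntensityGrid:
    """Read an 8-bit grayscale or RGB TIFF/PNG into an IntensityGrid."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return to_monochrome(arr, calibration_um_per_px)


def write_image(grid: IntensityGrid, path: str | Path) -> None:
    """Write an 8-bit grayscale image, clipping to [0, 255], round half up."""
    quantised = np.floor(np.clip(grid.values, 0, 255) + 0.5).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, quantised)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, quantised)


_METADATA_KEYS = (
    "donor_id",
    "group",
    "stress_dyn_cm2",
    "viscosity_mPas",
    "calibration_um_per_px",
)


def write_metadata(path: str | Path, **fields) -> None:
    """Write the per-image metadata sidecar (YAML)."""
    unknown = set(fields) - set(_METADATA_KEYS)
    if unknown:
        raise ValueError(f"unknown metadata keys: {sorted(unknown)}")
    with open(path, "w") as fh:
        yaml.safe_dump(fields, fh, sort_keys=True)


def read_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_METADATA_KEYS)
    if unknown:
        raise ValueError(f"unknown metadata keys: {sorted(unknown)}")
    return raw
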