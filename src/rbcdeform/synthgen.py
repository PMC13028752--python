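"""Synthetic microfluidic images and donor cohorts with known ground truth.

No raw study images are distributed with deformability assays of this
kind, so the package ships a generator for both levels of its data:

* **Images** — a streamline background (horizontal bands, sharp in Y,
  smoothly varying in X) with anti-aliased elliptical cells of known
  semi-axes rendered on top.  Every rendered cell's true deformability
  index (a − b)/(a + b) is recorded, so the image pipelines can be
  scored against ground truth.
* **Cohorts** — per-donor mean-DI tables across a shear-stress sweep,
  drawn from a saturating shear response DI(τ) = DI_max·τ/(τ_half + τ)
  with a Gaussian donor random intercept and residual noise, mirroring
  the repeated-measures design of a two-group deformability study.

Everything is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .core import DEFAULT_VISCOSITY_MPAS, IntensityGrid
from .deformability import stress_to_rate

__all__ = [
    "SyntheticCellSpec",
    "BackgroundSpec",
    "CellRanges",
    "GroundTruth",
    "CohortModel",
    "render_background",
    "render_cells",
    "generate_image",
    "expected_di",
    "generate_cohort",
    "fit_saturating_model",
    "REFERENCE_PROFILES",
]


@dataclass(frozen=True)
class SyntheticCellSpec:
    """One synthetic cell: an ellipse with semi-axes ``a >= b`` (pixels),
    orientation ``theta_deg`` and additive intensity ``amplitude``."""

    center_x: float
    center_y: float
    semi_major_a: float
    semi_minor_b: float
    theta_deg: float = 0.0
    amplitude: float = 60.0

    def __post_init__(self) -> None:
        if not (self.semi_major_a >= self.semi_minor_b > 0):
            raise ValueError("require semi_major_a >= semi_minor_b > 0")

    @property
    def true_di(self) -> float:
        """(a − b)/(a + b); identical for diameters since DI is scale-free."""
        a, b = self.semi_major_a, self.semi_minor_b
        return (a - b) / (a + b)

    @property
    def area(self) -> float:
        """Exact ellipse area πab in px²."""
        return math.pi * self.semi_major_a * self.semi_minor_b


@dataclass(frozen=True)
class BackgroundSpec:
    """Streamline background model.

    ``n_bands`` horizontal bands tile the frame; each band's intensity
    offset is a smooth random profile along X with 1/e autocorrelation
    length ``x_smoothness_scale`` and standard deviation
    ``band_amplitude``, so the background is smooth in X and sharp in Y
    (logistic band edges of width ``band_edge_sharpness``).
    """

    n_bands: int = 6
    band_edge_sharpness: float = 1.5
    x_smoothness_scale: float = 250.0
    base_level: float = 120.0
    band_amplitude: float = 12.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bands < 0:
            raise ValueError("n_bands must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_bands > 0 and self.x_smoothness_scale < 200.0:
            raise ValueError(
                "x_smoothness_scale below 200 px is not smooth relative to cells"
            )


@dataclass(frozen=True)
class CellRanges:
    """Sampling windows for synthetic cell parameters.

    Defaults emulate shear-elongated red cells at 0.6 µm/px: major
    diameters 5.8–8.2 µm, rendered areas within the 50–130 px segmentation
    window, and true DI between 0.13 and 0.27.
    """

    semi_major: tuple[float, float] = (4.8, 6.8)
    semi_minor: tuple[float, float] = (3.3, 4.9)
    theta_deg: tuple[float, float] = (-12.0, 12.0)
    amplitude: tuple[float, float] = (55.0, 80.0)
    di: tuple[float, float] = (0.13, 0.27)
    area_px: tuple[float, float] = (55.0, 125.0)

    def __post_init__(self) -> None:
        for name in ("semi_major", "semi_minor", "theta_deg", "amplitude",
                     "di", "area_px"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")


@dataclass
class GroundTruth:
    """Rendered-cell record: specs, true DIs, overlap flags, and the seed."""

    cells: list[SyntheticCellSpec] = field(default_factory=list)
    overlapping: list[bool] = field(default_factory=list)
    seed: int | None = None

    @property
    def true_dis(self) -> list[float]:
        return [c.true_di for c in self.cells]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_x": [c.center_x for c in self.cells],
                "center_y": [c.center_y for c in self.cells],
                "a": [c.semi_major_a for c in self.cells],
                "b": [c.semi_minor_b for c in self.cells],
                "theta_deg": [c.theta_deg for c in self.cells],
                "true_DI": self.true_dis,
            }
        )


# ---------------------------------------------------------------------------
# image synthesis


def _smooth_profile(rng: np.random.Generator, width: int, scale: float) -> np.ndarray:
    """Zero-mean unit-SD profile with 1/e autocorrelation length ``scale``.

    Gaussian-filtered white noise: a filter of sigma s gives
    autocorrelation exp(-d²/(4s²)), which crosses 1/e at d = 2s, so
    s = scale/2.
    """
    noise = rng.standard_normal(width)
    smooth = gaussian_filter1d(noise, sigma=scale / 2.0, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(width)
    return (smooth - smooth.mean()) / sd


def render_background(
    spec: BackgroundSpec,
    height: int,
    width: int,
    seed: int | np.random.Generator,
) -> IntensityGrid:
    """Render the streamline background; deterministic given the seed."""
    if height < 32 or width < 32:
        raise ValueError("background dimensions must be at least 32 px")
    rng = np.random.default_rng(seed)
    values = np.full((height, width), float(spec.base_level))
    if spec.n_bands > 0:
        y = np.arange(height, dtype=float)[:, None]
        edges = np.linspace(0, height, spec.n_bands + 1)
        sharp = max(spec.band_edge_sharpness, 1e-6)
        for b in range(spec.n_bands):
            # each band carries its own mean brightness (streamline bands
            # differ in intensity) plus a smooth along-X modulation
            dc = rng.standard_normal()
            profile = spec.band_amplitude * (
                dc + _smooth_profile(rng, width, spec.x_smoothness_scale)
            )
            lo, hi = edges[b], edges[b + 1]
            rise = 1.0 / (1.0 + np.exp(-(y - lo) / sharp))
            fall = 1.0 / (1.0 + np.exp(-(y - hi) / sharp))
            window = rise - fall if b < spec.n_bands - 1 else rise
            if b == 0:
                window = 1.0 - fall
            values += window * profile[None, :]
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=(height, width))
    return IntensityGrid(values)


def render_cells(
    grid: IntensityGrid,
    cells: list[SyntheticCellSpec],
    supersample: int = 4,
    bright: bool = True,
) -> tuple[IntensityGrid, GroundTruth]:
    """Add anti-aliased filled ellipses to a grid.

    Each pixel's added intensity is ``amplitude`` times its area coverage
    by the ellipse, estimated on a ``supersample``² subgrid.  Cells are
    rendered bright by default (both pipelines detect bright objects
    after filtering); ``bright=False`` subtracts instead.  Overlapping
    pairs (centre distance below the sum of semi-majors) are permitted
    but flagged in the returned ground truth.
    """
    values = grid.values.copy()
    h, w = values.shape
    sign = 1.0 if bright else -1.0
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    for cell in cells:
        r = max(cell.semi_major_a, cell.semi_minor_b) + 1.0
        x0 = max(int(math.floor(cell.center_x - r)), 0)
        x1 = min(int(math.ceil(cell.center_x + r)) + 1, w)
        y0 = max(int(math.floor(cell.center_y - r)), 0)
        y1 = min(int(math.ceil(cell.center_y + r)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1, dtype=float)[None, :, None, None] + offs[None, None, :, None]
        ys = np.arange(y0, y1, dtype=float)[:, None, None, None] + offs[None, None, None, :]
        dx = xs - cell.center_x
        dy = ys - cell.center_y
        th = math.radians(cell.theta_deg)
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        inside = (u / cell.semi_major_a) ** 2 + (v / cell.semi_minor_b) ** 2 <= 1.0
        coverage = inside.mean(axis=(2, 3))
        values[y0:y1, x0:x1] += sign * cell.amplitude * coverage
    overlapping = _overlap_flags(cells)
    return grid.with_values(values), GroundTruth(list(cells), overlapping)


def _overlap_flags(cells: list[SyntheticCellSpec]) -> list[bool]:
    flags = [False] * len(cells)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = math.hypot(
                cells[i].center_x - cells[j].center_x,
                cells[i].center_y - cells[j].center_y,
            )
            if d <= cells[i].semi_major_a + cells[j].semi_major_a:
                flags[i] = flags[j] = True
    return flags


def generate_image(
    background: BackgroundSpec,
    n_cells: int,
    ranges: CellRanges | None = None,
    seed: int | np.random.Generator = 0,
    height: int = 400,
    width: int = 400,
    allow_overlap: bool = False,
    max_attempts: int = 1000,
) -> tuple[IntensityGrid, GroundTruth]:
    """Background plus ``n_cells`` randomly placed, non-overlapping cells.

    Cell parameters are rejection-sampled uniformly within ``ranges``
    (the joint DI and area windows act as acceptance constraints); cells
    lie fully inside the frame.  With ``allow_overlap=False`` (default,
    since overlapping cells are excluded from analysis) candidate
    centres closer than the sum of semi-majors to an existing cell are
    rejected; after ``max_attempts`` failures an error reports how many
    cells were placed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    ranges = ranges or CellRanges()
    rng = np.random.default_rng(seed)
    grid = render_background(background, height, width, rng)
    cells: list[SyntheticCellSpec] = []
    for k in range(n_cells):
        placed = False
        for _ in range(max_attempts):
            a = rng.uniform(*ranges.semi_major)
            b = rng.uniform(*ranges.semi_minor)
            if b > a:
                continue
            di = (a - b) / (a + b)
            if not (ranges.di[0] <= di <= ranges.di[1]):
                continue
            if not (ranges.area_px[0] <= math.pi * a * b <= ranges.area_px[1]):
                continue
            margin = a + 2.0
            if 2 * margin >= min(height, width):
                continue
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
            if not allow_overlap and any(
                math.hypot(cx - c.center_x, cy - c.center_y)
                <= a + c.semi_major_a
                for c in cells
            ):
                continue
            cells.append(
                SyntheticCellSpec(
                    center_x=cx,
                    center_y=cy,
                    semi_major_a=a,
                    semi_minor_b=b,
                    theta_deg=rng.uniform(*ranges.theta_deg),
                    amplitude=rng.uniform(*ranges.amplitude),
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could only place {len(cells)} of {n_cells} cells after "
                f"{max_attempts} attempts each"
            )
    image, truth = render_cells(grid, cells)
    truth.seed = seed if isinstance(seed, int) else None
    return image, truth


# ---------------------------------------------------------------------------
# cohort synthesis

#: Published-scale mean DI versus shear stress (dyn/cm², 1..7) for each
#: pipeline and donor group; used to calibrate CohortModel defaults.
REFERENCE_PROFILES: dict[tuple[str, str], list[float]] = {
    ("dog", "healthy"): [0.157, 0.176, 0.191, 0.200, 0.205, 0.202, 0.204],
    ("dog", "cll"): [0.136, 0.151, 0.156, 0.159, 0.175, 0.181, 0.182],
    ("sinewin", "healthy"): [0.236, 0.271, 0.284, 0.293, 0.307, 0.291, 0.293],
    ("sinewin", "cll"): [0.201, 0.212, 0.221, 0.228, 0.233, 0.233, 0.219],
}


def fit_saturating_model(
    stresses: np.ndarray, di_means: np.ndarray
) -> tuple[float, float]:
    """Least-squares fit of DI(τ) = DI_max·τ/(τ_half + τ).

    Returns ``(DI_max, tau_half)``.
    """
    popt, _ = curve_fit(
        lambda t, dm, th: dm * t / (th + t),
        np.asarray(stresses, dtype=float),
        np.asarray(di_means, dtype=float),
        p0=[0.3, 0.5],
    )
    return float(popt[0]), float(popt[1])


@dataclass(frozen=True)
class CohortModel:
    """Two-group saturating shear-response model for cohort simulation.

    Group defaults are least-squares fits of the saturating model to the
    mean healthy and CLL DI profiles measured with the
    difference-of-Gaussians pipeline; donor and residual SDs are set so
    that the between-donor spread at a given shear matches the
    0.01–0.015 observed in such cohorts.
    """

    di_max: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.2173, "cll": 0.1873}
    )
    tau_half: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.4024, "cll": 0.4373}
    )
    donor_sd: float = 0.010
    residual_sd: float = 0.006
    n_donors: dict[str, int] = field(
        default_factory=lambda: {"healthy": 13, "cll": 9}
    )
    stresses_dyn_cm2: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    viscosity_mPas: float = DEFAULT_VISCOSITY_MPAS

    def __post_init__(self) -> None:
        for g, dm in self.di_max.items():
            if not 0 < dm < 1:
                raise ValueError(f"di_max[{g!r}] must lie in (0, 1)")
        for g, th in self.tau_half.items():
            if not th > 0:
                raise ValueError(f"tau_half[{g!r}] must be positive")
        if self.donor_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be non-negative")
        for g, n in self.n_donors.items():
            if n < 1:
                raise ValueError(f"n_donors[{g!r}] must be >= 1")


def expected_di(stress_dyn_cm2: float, model: CohortModel, group: str) -> float:
    """Noise-free group mean DI at shear stress τ: DI_max·τ/(τ_half + τ)."""
    if not stress_dyn_cm2 > 0:
        raise ValueError("stress must be positive")
    if group not in model.di_max:
        raise KeyError(f"unknown group label {group!r}")
    return (
        model.di_max[group]
        * stress_dyn_cm2
        / (model.tau_half[group] + stress_dyn_cm2)
    )


def generate_cohort(
    model: CohortModel, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Simulate a repeated-measures cohort table.

    One row per donor × shear stress: DI(donor, τ) = expected_di(τ, group)
    + donor intercept ~ N(0, donor_sd²) + noise ~ N(0, residual_sd²),
    clipped to [0.01, 0.99].  Columns: donor_id, group, stress_dyn_cm2,
    shear_rate_s1, di_mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(model.n_donors):
        for d in range(model.n_donors[group]):
            donor_id = f"{group}_{d + 1:02d}"
            intercept = rng.normal(0.0, model.donor_sd) if model.donor_sd else 0.0
            for tau in model.stresses_dyn_cm2:
                noise = (
                    rng.normal(0.0, model.residual_sd) if model.residual_sd else 0.0
                )
                di = expected_di(tau, model, group) + intercept + noise
                rows.append(
                    {
                        "donor_id": donor_id,
                        "group": group,
                        "stress_dyn_cm2": tau,
                        "shear_rate_s1": stress_to_rate(tau, model.viscosity_mPas),
                        "di_mean": float(np.clip(di, 0.01, 0.99)),
                    }
                )
    return pd.DataFrame(rows)
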