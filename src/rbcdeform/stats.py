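"""Statistical layer: normality/group tests, mixed-effects modeling with
Satterthwaite degrees of freedom and partial eta squared, Pearson
correlation, and Bland–Altman method agreement.

The central model is a linear mixed model for the repeated-measures
design of a deformability study: each donor contributes one mean DI per
shear condition, donor identity is a random intercept, and group
(patient vs. control), shear rate (categorical) and their interaction
are fixed effects,

    DI_ij = β₀ + group_i + shear_j + (group × shear)_ij + u_i + ε_ij,
    u_i ~ N(0, σ_d²),  ε_ij ~ N(0, σ_e²).

Fixed effects are tested with Type III F statistics whose denominator
degrees of freedom use the Satterthwaite approximation, and effect sizes
are reported as partial eta squared, η²p = F·df1/(F·df1 + df2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "EffectResult",
    "MixedModelResult",
    "AgreementResult",
    "shapiro_wilk",
    "mann_whitney",
    "groupwise_mann_whitney",
    "fit_mixed_model",
    "partial_eta_squared",
    "pearson",
    "bland_altman",
]


# ---------------------------------------------------------------------------
# simple tests


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test: returns (W, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant data")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U test, two-sided.

    The exact null distribution is enumerated when the smaller sample
    has at most 8 observations and there are no ties; otherwise the
    normal approximation with tie correction is used.  U is reported
    for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    small = min(a.size, b.size) <= 8
    if small and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def groupwise_mann_whitney(
    cohort: pd.DataFrame,
    value_col: str = "di_mean",
    group_col: str = "group",
    by: str = "stress_dyn_cm2",
    holm: bool = False,
) -> pd.DataFrame:
    """Two-group Mann–Whitney test at each shear condition.

    Mirrors per-shear group comparisons; no multiplicity correction by
    default, Holm step-down optionally (``holm=True``).
    """
    levels = sorted(cohort[group_col].unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    rows = []
    for key, sub in cohort.groupby(by, sort=True):
        u, p = mann_whitney(
            sub.loc[sub[group_col] == levels[0], value_col],
            sub.loc[sub[group_col] == levels[1], value_col],
        )
        rows.append({by: key, "U": u, "p": p})
    out = pd.DataFrame(rows)
    if holm:
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
    return out


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Effect size of a fixed effect: η²p = F·df1/(F·df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 < 1 or df2 <= 0:
        raise ValueError("require df1 >= 1 and df2 > 0")
    return F * df1 / (F * df1 + df2)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bland–Altman agreement


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of paired measurements (differences x − y)."""

    bias: float
    loa_low: float
    loa_high: float
    pct_within: float
    prop_bias_slope: float
    prop_bias_p: float
    n: int


def bland_altman(x, y) -> AgreementResult:
    """Method agreement via mean bias and 95% limits of agreement.

    d = x − y; bias = mean(d); limits = bias ± 1.96·SD(d) (sample SD);
    ``pct_within`` is the fraction of differences inside the limits.
    Proportional bias is the OLS slope of d on the pairwise means
    (x + y)/2 with its two-sided t test.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired series must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    d = xa - ya
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((d >= loa_low) & (d <= loa_high)))
    means = (xa + ya) / 2.0
    if np.ptp(d) == 0 or np.ptp(means) == 0:
        slope, p = 0.0, 1.0
    else:
        reg = sps.linregress(means, d)
        slope, p = float(reg.slope), float(reg.pvalue)
        if not np.isfinite(p):
            p = 1.0
    return AgreementResult(bias, loa_low, loa_high, within, slope, p, int(xa.size))


# ---------------------------------------------------------------------------
# linear mixed model with Satterthwaite df


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float
    eta2p: float


@dataclass
class MixedModelResult:
    """Type III fixed-effect tests of the random-intercept model."""

    effects: dict[str, EffectResult]
    donor_variance: float
    residual_variance: float
    fixed_effects: dict[str, float] = field(default_factory=dict)
    fixed_effects_se: dict[str, float] = field(default_factory=dict)
    converged: bool = True


def _sum_coded_design(
    cohort: pd.DataFrame, shear_col: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, slice], list[str]]:
    """Deviation-coded (sum-to-zero) design for group * shear.

    With sum coding, testing the coefficient block of each term gives
    Type III tests directly.
    """
    groups = sorted(cohort["group"].unique())
    shears = sorted(cohort[shear_col].unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    if len(shears) < 2:
        raise ValueError("need at least two shear levels")
    counts = cohort.groupby("group")["donor_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least two donors per group")
    s = len(shears)
    g_code = np.where(cohort["group"] == groups[0], 1.0, -1.0)
    shear_idx = cohort[shear_col].map({v: i for i, v in enumerate(shears)}).to_numpy()
    S = np.zeros((len(cohort), s - 1))
    for j in range(s - 1):
        S[shear_idx == j, j] = 1.0
    S[shear_idx == s - 1, :] = -1.0
    X = np.column_stack([np.ones(len(cohort)), g_code, S, g_code[:, None] * S])
    names = (
        ["intercept", "group"]
        + [f"shear[{shears[j]}]" for j in range(s - 1)]
        + [f"group:shear[{shears[j]}]" for j in range(s - 1)]
    )
    terms = {
        "group": slice(1, 2),
        "shear": slice(2, 2 + (s - 1)),
        "group:shear": slice(2 + (s - 1), 2 + 2 * (s - 1)),
    }
    y = cohort["di_mean"].to_numpy(dtype=float)
    donor_codes = pd.factorize(cohort["donor_id"])[0]
    return y, X, donor_codes, terms, names


def _group_blocks(donor_codes: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(donor_codes == g) for g in np.unique(donor_codes)]


def _beta_cov(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed-effect estimate and covariance for θ = (σ_d², σ_e²)."""
    sd2, se2 = theta
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    for idx in blocks:
        Xg, yg = X[idx], y[idx]
        n_g = idx.size
        c = sd2 / (se2 + n_g * sd2)
        x1 = Xg.sum(axis=0)
        y1 = yg.sum()
        XtViX += (Xg.T @ Xg - c * np.outer(x1, x1)) / se2
        XtViy += (Xg.T @ yg - c * x1 * y1) / se2
    cov = np.linalg.inv(XtViX)
    beta = cov @ XtViy
    return beta, cov


def _reml_loglik(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, blocks: list[np.ndarray]
) -> float:
    """Restricted log-likelihood of the random-intercept model (up to a
    constant), evaluated in closed form via the Woodbury identity."""
    sd2, se2 = theta
    if se2 <= 0 or sd2 < 0:
        return -np.inf
    p = X.shape[1]
    logdet_V = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    for idx in blocks:
        Xg, yg = X[idx], y[idx]
        n_g = idx.size
        c = sd2 / (se2 + n_g * sd2)
        logdet_V += (n_g - 1) * np.log(se2) + np.log(se2 + n_g * sd2)
        x1 = Xg.sum(axis=0)
        y1 = yg.sum()
        XtViX += (Xg.T @ Xg - c * np.outer(x1, x1)) / se2
        XtViy += (Xg.T @ yg - c * x1 * y1) / se2
        ytViy += (yg @ yg - c * y1 * y1) / se2
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - XtViy @ beta
    return -0.5 * (logdet_V + logdet_XtViX + quad)


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = theta.size
    h = np.maximum(np.abs(theta), 1e-10) * rel_step
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _numerical_gradient(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    h = np.maximum(np.abs(theta), 1e-10) * rel_step
    g = np.zeros_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta); e[i] = h[i]
        g[i] = (f(theta + e) - f(theta - e)) / (2 * h[i])
    return g


def fit_mixed_model(
    cohort: pd.DataFrame, shear_col: str | None = None
) -> MixedModelResult:
    """Fit the random-intercept mixed model and test fixed effects.

    ``cohort`` needs columns ``donor_id``, ``group``, ``di_mean`` and a
    shear column (``stress_dyn_cm2`` or ``shear_rate_s1``); shear enters
    as a categorical factor.  The variance components are estimated by
    REML (statsmodels MixedLM); each fixed-effect block is then tested
    with a Type III F statistic whose denominator df follow the
    Satterthwaite approximation: the covariance of the REML variance
    estimates is taken from the numerical Hessian of the restricted
    likelihood, and each eigencomponent of the contrast covariance
    contributes df ν = 2λ²/(∇λᵀ A ∇λ).
    """
    if shear_col is None:
        shear_col = (
            "stress_dyn_cm2" if "stress_dyn_cm2" in cohort.columns else "shear_rate_s1"
        )
    for col in ("donor_id", "group", "di_mean", shear_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    y, X, donor_codes, terms, names = _sum_coded_design(cohort, shear_col)
    blocks = _group_blocks(donor_codes)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=donor_codes)
        fit = model.fit(reml=True)
    theta = np.array(
        [max(float(np.asarray(fit.cov_re)[0, 0]), 1e-12), float(fit.scale)]
    )
    beta, cov_beta = _beta_cov(theta, y, X, blocks)

    loglik = lambda th: _reml_loglik(th, y, X, blocks)
    H = _numerical_hessian(loglik, theta)
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(-H)

    effects: dict[str, EffectResult] = {}
    for term, sl in terms.items():
        L = np.zeros((sl.stop - sl.start, X.shape[1]))
        for r, c in enumerate(range(sl.start, sl.stop)):
            L[r, c] = 1.0
        q = L.shape[0]
        Lb = L @ beta
        Lam = L @ cov_beta @ L.T
        evals, evecs = np.linalg.eigh(Lam)
        F = 0.0
        nus = []
        for i in range(q):
            u = evecs[:, i]
            lam = evals[i]
            if lam <= 0:
                continue
            F += float((u @ Lb) ** 2 / lam)
            f_i = lambda th, u=u: float(
                u @ (L @ _beta_cov(th, y, X, blocks)[1] @ L.T) @ u
            )
            g = _numerical_gradient(f_i, theta)
            denom = float(g @ A @ g)
            nus.append(2.0 * lam**2 / denom if denom > 0 else np.inf)
        F /= q
        finite = [nu for nu in nus if nu > 2]
        E = sum(nu / (nu - 2.0) for nu in finite)
        df2 = 2.0 * E / (E - q) if E > q else float("nan")
        p = float(sps.f.sf(F, q, df2)) if np.isfinite(df2) else float("nan")
        eta2p = partial_eta_squared(F, q, df2) if np.isfinite(df2) else float("nan")
        effects[term] = EffectResult(F=float(F), df1=float(q), df2=float(df2),
                                     p=p, eta2p=eta2p)

    return MixedModelResult(
        effects=effects,
        donor_variance=float(theta[0]),
        residual_variance=float(theta[1]),
        fixed_effects=dict(zip(names, map(float, beta))),
        fixed_effects_se=dict(
            zip(names, map(float, np.sqrt(np.diag(cov_beta))))
        ),
        converged=bool(getattr(fit, "converged", True)),
    )
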