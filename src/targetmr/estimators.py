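"""Causal-effect estimators for two-sample MR on harmonized instruments.

The per-instrument building block is the ratio estimate
theta_j = beta_y_j / beta_x_j with first-order standard error
se_y_j / |beta_x_j| (exposure-side uncertainty ignored, the two-sample
convention).  A single instrument gives the Wald ratio; k >= 2 are combined
by fixed-effect inverse-variance weighting; k >= 3 additionally supports
MR-Egger (weighted regression with intercept as the average-pleiotropy
estimate), the weighted median, and the weighted mode.  Estimates are
reported as odds ratios per a configurable change in exposure — by default
per 0.1 unit *lower* exposure, i.e. scale factor -0.1 on the log-odds
per-unit estimate — with normal-theory confidence intervals and p-values,
and a Bonferroni significance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "RatioEstimate",
    "MrResult",
    "MrConfig",
    "wald_ratio",
    "ivw_fixed",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "scale_estimate",
    "wald_summary",
    "implied_se",
    "bonferroni_gate",
    "run_mr",
]

Z_95 = 1.96  # conventional normal quantile for 95% intervals


@dataclass(frozen=True)
class RatioEstimate:
    """Single-instrument ratio estimate theta = beta_y / beta_x."""

    rsid: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise ValueError(f"{self.rsid}: se_theta must be positive")

    @property
    def weight(self) -> float:
        return self.se_theta**-2


@dataclass
class MrResult:
    """One method's causal-effect estimate for one drug class."""

    drug_class: str
    method: str  # wald | ivw | egger | weighted_median | weighted_mode
    theta: float  # log-odds of outcome per +1 unit of exposure
    se: float
    n_instruments: int
    mean_f: float = float("nan")
    scale_factor: float = -0.1
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    # filled by finalize()
    or_scaled: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    pval: float = float("nan")
    bonferroni_significant: bool | None = None

    def finalize(self, alpha: float = 0.05, n_tests: int = 6) -> "MrResult":
        """Attach the scaled OR, its CI, the p-value and the Bonferroni flag."""
        self.or_scaled, self.ci_low, self.ci_high = scale_estimate(
            self.theta, self.se, self.scale_factor
        )
        _, _, self.pval = wald_summary(self.scale_factor * self.theta, abs(self.scale_factor) * self.se)
        self.bonferroni_significant = bonferroni_gate(self.pval, alpha, n_tests)
        return self


@dataclass(frozen=True)
class MrConfig:
    """Estimation settings shared across methods."""

    scale_factor: float = -0.1
    alpha: float = 0.05
    n_tests: int = 6
    bootstrap_reps: int = 10_000
    mode_phi: float = 1.0
    seed: int = 0


def _ratios(hs: list[HarmonizedInstrument]) -> list[RatioEstimate]:
    out = []
    for h in hs:
        if h.beta_x == 0:
            raise ZeroDivisionError(f"{h.rsid}: exposure effect is zero; ratio undefined")
        out.append(RatioEstimate(h.rsid, h.beta_y / h.beta_x, h.se_y / abs(h.beta_x)))
    return out


def wald_ratio(h: HarmonizedInstrument) -> RatioEstimate:
    """Ratio estimate for a single instrument (first-order delta-method se)."""
    return _ratios([h])[0]


def ivw_fixed(hs: list[HarmonizedInstrument]) -> tuple[float, float]:
    """Fixed-effect inverse-variance-weighted estimate (theta_hat, se).

    Weights are w_j = beta_x_j² / se_y_j², the inverse ratio-estimate
    variances; with one instrument this reduces exactly to the Wald ratio.
    """
    if not hs:
        raise ValueError("ivw_fixed requires at least one instrument")
    ratios = _ratios(hs)
    w = np.array([r.weight for r in ratios])
    theta = np.array([r.theta for r in ratios])
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta_hat, se


def mr_egger(hs: list[HarmonizedInstrument]) -> tuple[float, float, float, float]:
    """MR-Egger regression: (slope, slope_se, intercept, intercept_se).

    Weighted least squares of beta_y on beta_x with intercept, weights
    1/se_y², after orienting every instrument so beta_x >= 0 (the estimator
    is not invariant to allele orientation otherwise).  Standard errors use
    a multiplicative overdispersion factor floored at 1.
    """
    if len(hs) < 3:
        raise ValueError("mr_egger requires at least 3 instruments")
    bx = np.array([h.beta_x for h in hs])
    by = np.array([h.beta_y for h in hs])
    sy = np.array([h.se_y for h in hs])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = len(hs) - 2
    dispersion = max(1.0, float(np.sum(w * resid**2) / dof))
    cov = dispersion * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    return slope, float(math.sqrt(cov[1, 1])), intercept, float(math.sqrt(cov[0, 0]))


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted empirical 0.5-quantile with linear interpolation.

    Cumulative weight of the j-th order statistic is s_j = sum_{i<=j} w_i -
    w_j/2 on normalized weights; the estimate interpolates between the
    order statistics bracketing s = 0.5.
    """
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def _mode_bandwidth(theta: np.ndarray, phi: float) -> float:
    k = theta.size
    sd = float(np.std(theta, ddof=1))
    mad = float(stats.median_abs_deviation(theta, scale=1.0)) * 1.4826
    return phi * 0.9 * min(sd, mad) * k ** (-1.0 / 5.0)


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of a weighted normal-kernel density over the ratio estimates."""
    h = _mode_bandwidth(theta, phi)
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: all (or almost all) ratios identical
        return float(np.median(theta))
    wn = w / np.sum(w)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    dens = (wn[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def _parametric_bootstrap_se(
    hs: list[HarmonizedInstrument],
    point_fn,
    reps: int,
    seed: int,
) -> float:
    """Bootstrap se: resample beta_x, beta_y from their normal sampling
    distributions and recompute the point estimate."""
    rng = np.random.default_rng(seed)
    bx = np.array([h.beta_x for h in hs])
    by = np.array([h.beta_y for h in hs])
    sx = np.array([h.se_x for h in hs])
    sy = np.array([h.se_y for h in hs])
    ests = np.empty(reps)
    for i in range(reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0.0] = np.finfo(float).tiny  # guard degenerate draw
        theta = bys / bxs
        w = bxs**2 / sy**2
        ests[i] = point_fn(theta, w)
    return float(np.std(ests, ddof=1))


def weighted_median(
    hs: list[HarmonizedInstrument], bootstrap_reps: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Weighted-median estimate (theta_hat, bootstrap se).

    Consistent when instruments carrying at least half the weight are valid.
    """
    if len(hs) < 3:
        raise ValueError("weighted_median requires at least 3 instruments")
    ratios = _ratios(hs)
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    point = _weighted_median_point(theta, w)
    se = _parametric_bootstrap_se(hs, _weighted_median_point, bootstrap_reps, seed)
    return point, se


def weighted_mode(
    hs: list[HarmonizedInstrument],
    phi: float = 1.0,
    bootstrap_reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Weighted-mode estimate (theta_hat, bootstrap se).

    Consistent when the largest group of instruments sharing a ratio value
    is valid; ``phi`` scales the kernel bandwidth.
    """
    if len(hs) < 3:
        raise ValueError("weighted_mode requires at least 3 instruments")
    ratios = _ratios(hs)
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    if np.allclose(theta, theta[0]):
        return float(theta[0]), 0.0
    point = _weighted_mode_point(theta, w, phi)
    se = _parametric_bootstrap_se(
        hs, lambda t, ww: _weighted_mode_point(t, ww, phi), bootstrap_reps, seed
    )
    return point, se


def scale_estimate(
    theta_hat: float, se: float, factor: float = -0.1
) -> tuple[float, float, float]:
    """Rescale a per-unit log-odds estimate to an OR per `factor` units.

    factor = -0.1 expresses the estimate per 0.1 unit *decrease* in the
    exposure.  Returns (OR, ci_low, ci_high) with the CI bounds ordered.
    """
    if not se > 0:
        raise ValueError("se must be positive")
    log_or = factor * theta_hat
    half = Z_95 * abs(factor) * se
    return math.exp(log_or), math.exp(log_or - half), math.exp(log_or + half)


def wald_summary(log_or: float, se: float) -> tuple[float, tuple[float, float], float]:
    """Normal-theory summary of a log-OR: (OR, 95% CI, two-sided p)."""
    if not se > 0:
        raise ValueError("se must be positive")
    p = float(2.0 * stats.norm.sf(abs(log_or) / se))
    ci = (math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se))
    return math.exp(log_or), ci, p


def implied_se(odds_ratio: float, pval: float) -> float:
    """Standard error implied by a printed OR and two-sided p-value.

    Inverts p = 2*Phi(-|ln OR| / se); used to reconstruct confidence
    intervals from rounded published numbers.
    """
    z = float(stats.norm.isf(pval / 2.0))
    return abs(math.log(odds_ratio)) / z


def bonferroni_gate(pval: float, alpha: float = 0.05, n_tests: int = 6) -> bool:
    """Strict multiple-testing gate: True iff pval < alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < pval <= 1.0:
        raise ValueError("pval must lie in (0,1]")
    return pval < alpha / n_tests


def run_mr(
    hs: list[HarmonizedInstrument],
    drug_class: str = "",
    config: MrConfig = MrConfig(),
    mean_f: float = float("nan"),
) -> list[MrResult]:
    """Dispatch the estimator battery by instrument count.

    k = 1: Wald ratio only; k = 2: IVW; k >= 3: IVW plus MR-Egger, weighted
    median and weighted mode.  k = 0 returns an empty list ("no valid
    instruments").  All results are scaled, given CIs/p-values and the
    Bonferroni flag.
    """
    k = len(hs)
    results: list[MrResult] = []

    def make(method: str, theta: float, se: float, **kw) -> MrResult:
        res = MrResult(
            drug_class=drug_class,
            method=method,
            theta=theta,
            se=se,
            n_instruments=k,
            mean_f=mean_f,
            scale_factor=config.scale_factor,
            **kw,
        )
        return res.finalize(config.alpha, config.n_tests)

    if k == 0:
        return results
    if k == 1:
        r = wald_ratio(hs[0])
        results.append(make("wald", r.theta, r.se_theta))
        return results

    theta, se = ivw_fixed(hs)
    results.append(make("ivw", theta, se))
    if k >= 3:
        slope, slope_se, intc, intc_se = mr_egger(hs)
        results.append(
            make("egger", slope, slope_se, egger_intercept=intc, egger_intercept_se=intc_se)
        )
        wm, wm_se = weighted_median(hs, config.bootstrap_reps, config.seed)
        results.append(make("weighted_median", wm, wm_se))
        mo, mo_se = weighted_mode(hs, config.mode_phi, config.bootstrap_reps, config.seed + 1)
        results.append(make("weighted_mode", mo, mo_se))
    return results
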