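"""Approximate-Bayes-factor colocalization of two regional association signals.

Under a single-causal-variant-per-trait assumption, each variant's evidence
of association with a trait is summarized by Wakefield's approximate Bayes
factor.  With z = beta/se and shrinkage r = W/(W + se²), the log ABF of
association versus the null is

    log ABF = 0.5 * log(1 - r) + 0.5 * r * z²

where W is the prior variance of the effect size.  Regional evidence for
the five hypotheses — H0 no association, H1/H2 one trait only, H3 two
distinct causal variants, H4 one shared causal variant — is accumulated
from per-variant ABFs with priors p1, p2 (a variant is causal for trait
1/2) and p12 (causal for both).  All sums run in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ColocConfig",
    "ColocResult",
    "wakefield_log_abf",
    "trait_abf",
    "coloc_posteriors",
    "estimate_trait_sd",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocConfig:
    """Priors for the five-hypothesis colocalization model.

    ``w_continuous`` is the prior effect-size standard deviation on the
    standardized (per trait-sd) scale for quantitative traits;
    ``w_binary`` is on the log-odds scale for case-control traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_continuous: float = 0.15
    w_binary: float = 0.2

    def __post_init__(self) -> None:
        # p12 = 0 is admitted as the explicit "no shared variant" prior
        if not (0.0 <= self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ValueError("priors must satisfy 0 <= p12 <= min(p1, p2) < 1")
        if not (self.p1 > 0.0 and self.p2 > 0.0):
            raise ValueError("p1 and p2 must be positive")


@dataclass
class ColocResult:
    region: str
    n_variants: int
    posteriors: dict[str, float]
    config: ColocConfig = field(default_factory=ColocConfig)

    @property
    def pp_h4(self) -> float:
        return self.posteriors["H4"]


def wakefield_log_abf(beta: float, se: float, W: float) -> float:
    """Log approximate Bayes factor of association versus the null."""
    if not se > 0:
        raise ValueError("se must be positive")
    if W < 0:
        raise ValueError("prior variance W must be non-negative")
    if W == 0:
        return 0.0
    z = beta / se
    r = W / (W + se * se)
    return 0.5 * math.log1p(-r) + 0.5 * r * z * z


def estimate_trait_sd(eaf: np.ndarray, se: np.ndarray, n: np.ndarray) -> float:
    """Phenotype standard deviation implied by allelic-scale standard errors.

    For a linear GWAS, var(beta_hat_j) ≈ sd_Y² / (n_j · 2 p_j (1-p_j)), so
    each variant implies sd_Y² ≈ se_j² · n_j · 2 p_j (1-p_j); the median
    across variants is robust to outliers.
    """
    implied = se**2 * n * 2.0 * eaf * (1.0 - eaf)
    return float(np.sqrt(np.median(implied)))


def trait_abf(
    beta: np.ndarray,
    se: np.ndarray,
    trait_type: str,
    config: ColocConfig = ColocConfig(),
    trait_sd: float | None = None,
    eaf: np.ndarray | None = None,
    n: np.ndarray | None = None,
) -> np.ndarray:
    """Per-variant log ABFs for one trait with the standard prior variance.

    Continuous traits use W = (w_continuous · sd_Y)² on the trait's own
    scale; sd_Y is supplied or estimated from (eaf, se, n).  Binary traits
    use W = w_binary² on the log-odds scale.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if trait_type == "binary":
        W = config.w_binary**2
    elif trait_type == "continuous":
        if trait_sd is None:
            if eaf is None or n is None:
                raise ValueError("continuous trait needs trait_sd or (eaf, n) to estimate it")
            trait_sd = estimate_trait_sd(np.asarray(eaf, float), se, np.asarray(n, float))
        W = (config.w_continuous * trait_sd) ** 2
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    return np.array([wakefield_log_abf(b, s, W) for b, s in zip(beta, se)])


def coloc_posteriors(
    log_abf_x: np.ndarray,
    log_abf_y: np.ndarray,
    config: ColocConfig = ColocConfig(),
    region: str = "",
) -> ColocResult:
    """Posterior probabilities of H0–H4 from per-variant log ABFs.

    The unnormalized hypothesis sums are
      S0 = 1, S1 = p1 Σ A_j, S2 = p2 Σ B_j,
      S3 = p1 p2 (Σ A · Σ B − Σ A_j B_j), S4 = p12 Σ A_j B_j
    with A, B the per-variant ABFs; everything is evaluated in log space,
    with S3 via the product-minus-diagonal identity (the rare negative
    cancellation is clamped to zero with a warning).
    """
    la = np.asarray(log_abf_x, dtype=float)
    lb = np.asarray(log_abf_y, dtype=float)
    if la.shape != lb.shape:
        raise ValueError(f"ABF vectors differ in length: {la.shape} vs {lb.shape}")
    if la.size == 0:
        raise ValueError("at least one variant required")

    l_sum_a = float(logsumexp(la))
    l_sum_b = float(logsumexp(lb))
    l_sum_ab = float(logsumexp(la + lb))

    log_s = np.full(5, -np.inf)
    log_s[0] = 0.0
    log_s[1] = math.log(config.p1) + l_sum_a
    log_s[2] = math.log(config.p2) + l_sum_b
    # S3 ∝ Σ_j≠k A_j B_k = ΣA·ΣB − Σ A_j B_j
    l_prod = l_sum_a + l_sum_b
    if la.size == 1:
        pass  # no distinct-variant configuration exists: S3 = 0
    else:
        diff = l_sum_ab - l_prod
        if diff >= 0.0:
            if diff > 1e-9:
                warnings.warn("cross-product sum below diagonal sum; clamping S3 to 0")
            # diagonal exhausts the product to within rounding: S3 = 0
        else:
            log_s[3] = math.log(config.p1) + math.log(config.p2) + l_prod + math.log1p(-math.exp(diff))
    if config.p12 > 0.0:
        log_s[4] = math.log(config.p12) + l_sum_ab

    log_total = float(logsumexp(log_s))
    pp = np.exp(log_s - log_total)
    return ColocResult(
        region=region,
        n_variants=int(la.size),
        posteriors={h: float(p) for h, p in zip(HYPOTHESES, pp)},
        config=config,
    )
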