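"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are drawn directly from their asymptotic sampling
distribution rather than from individual-level genotypes.  On the
standardized-genotype scale, marginal exposure effects follow

    b_x ~ MVN(R beta,  R * sigma_x^2 / n_x)

and marginal outcome (log-odds) effects follow

    b_y ~ MVN(R (theta beta + alpha),  R * c / n_y),   c = 1 / (phi (1 - phi))

where R is the signed LD correlation matrix, beta the sparse causal
exposure effects, theta the causal effect of exposure on outcome, alpha
per-variant direct (pleiotropic) effects, phi the outcome case fraction,
and c the logistic-score variance factor.  Standard errors are set to the
theoretical values, effects are converted to the allelic scale via
1/sqrt(2 maf (1 - maf)), and p-values come from two-sided normal theory.
The exposure and outcome samples are drawn independently (two-sample
design, no overlap).

Defaults emulate the study conditions this pipeline targets: a continuous
glucose GWAS of N = 309,895 and an RA case-control GWAS of 22,350 cases /
74,823 controls, with a 1000-Genomes-like AR(1) LD panel over a drug-target
cis region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .sumstats import (
    GwasRecord,
    LdReference,
    SummaryDataset,
    get_drug_target,
)

__all__ = [
    "SimulationConfig",
    "PRESETS",
    "make_ld_ar1",
    "simulate_two_sample",
    "preset",
    "flip_outcome_alleles",
]

# non-palindromic allele pairs only, so strand ambiguity never silently
# removes a scenario's causal variant; strand flips are injected explicitly
# via flip_outcome_alleles when a test needs them
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one two-sample region simulation.

    ``beta`` and ``alpha`` are per-variant effect vectors on the
    standardized-genotype scale (exposure: mmol/L per genotype sd; direct
    outcome effects: log-odds per genotype sd); ``theta`` is the causal
    effect of exposure on outcome in log-odds per mmol/L.
    """

    seed: int
    M: int = 50
    drug_class: str = "Thiazolidinediones"
    rho: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    beta: tuple[float, ...] = ()
    theta: float = 0.0
    alpha: tuple[float, ...] = ()
    n_x: int = 309_895
    n_cases: int = 22_350
    n_controls: int = 74_823
    sigma_x: float = 0.8  # phenotype sd of blood glucose, mmol/L
    # scale on which alpha is expressed: direct effects per genotype sd
    # ("standardized") or per allele ("allelic"); allelic-scale injection
    # keeps a constant pleiotropic offset constant after MAF conversion
    alpha_scale: str = "standardized"

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")
        if self.n_x < 2 or (self.n_cases + self.n_controls) < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.beta and len(self.beta) != self.M:
            raise ValueError("beta must have length M")
        if self.alpha and len(self.alpha) != self.M:
            raise ValueError("alpha must have length M")
        if self.alpha_scale not in ("standardized", "allelic"):
            raise ValueError("alpha_scale must be 'standardized' or 'allelic'")

    @property
    def n_y(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_y

    def beta_vec(self) -> np.ndarray:
        return np.array(self.beta) if self.beta else np.zeros(self.M)

    def alpha_vec(self) -> np.ndarray:
        return np.array(self.alpha) if self.alpha else np.zeros(self.M)


def make_ld_ar1(M: int, rho: float) -> LdReference:
    """AR(1) LD panel: r[i,j] = rho^|i-j| (positive definite for |rho| < 1)."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    idx = np.arange(M)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    rsids = [f"rs{100000 + i}" for i in range(M)]
    return LdReference(rsids, r)


def _sparse(M: int, entries: dict[int, float]) -> tuple[float, ...]:
    v = np.zeros(M)
    for i, x in entries.items():
        v[i] = x
    return tuple(v)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, LdReference, dict]:
    """Draw one exposure/outcome summary-statistic pair plus its LD panel.

    Returns (exposure dataset, outcome dataset, LD panel, truth record); the
    truth record carries the generative parameters, variant positions and
    causal indices for downstream scoring.  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    M = config.M
    panel = make_ld_ar1(M, config.rho)
    R = panel.r
    chol = np.eye(M) if config.rho == 0.0 else np.linalg.cholesky(R)

    target = get_drug_target(config.drug_class)
    chrom = target.genes[0].chrom
    lo = min(g.start for g in target.genes)
    hi = max(g.end for g in target.genes)
    positions = np.unique(np.linspace(lo, hi, M).round().astype(int))
    while positions.size < M:  # spans narrower than M bp: force distinct ints
        positions = np.arange(lo, lo + M)

    mafs = rng.uniform(config.maf_low, config.maf_high, M)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), M)

    beta = config.beta_vec()
    alpha = config.alpha_vec()
    if config.alpha_scale == "allelic":
        # per-allele direct effects: convert to the standardized scale the
        # MVN draw operates on (b_std = b_allelic * sqrt(2 maf (1-maf)))
        alpha = alpha * np.sqrt(2.0 * mafs * (1.0 - mafs))
    se_x_std = config.sigma_x / np.sqrt(config.n_x)
    phi = config.case_fraction
    c = 1.0 / (phi * (1.0 - phi))
    se_y_std = np.sqrt(c / config.n_y)

    b_x = R @ beta + se_x_std * (chol @ rng.standard_normal(M))
    b_y = R @ (config.theta * beta + alpha) + se_y_std * (chol @ rng.standard_normal(M))

    scale = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs))  # std-genotype -> per-allele

    def dataset(name, trait_type, b_std, se_std, n, unit="", **kw) -> SummaryDataset:
        ds = SummaryDataset(trait_name=name, trait_type=trait_type, unit=unit, **kw)
        b = b_std * scale
        se = np.full(M, se_std) * scale
        z = b / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        for i in range(M):
            ea, oa = _ALLELE_PAIRS[pair_idx[i]]
            ds.add(
                GwasRecord(
                    chrom=chrom,
                    pos=int(positions[i]),
                    rsid=panel.rsids[i],
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=float(mafs[i]),
                    beta=float(b[i]),
                    se=float(se[i]),
                    pval=float(p[i]),
                    n=int(n),
                )
            )
        return ds

    exposure = dataset("blood glucose", "continuous", b_x, se_x_std, config.n_x, unit="mmol/L")
    outcome = dataset(
        "RA",
        "binary",
        b_y,
        se_y_std,
        config.n_y,
        n_cases=config.n_cases,
        n_controls=config.n_controls,
    )
    truth = {
        "seed": config.seed,
        "drug_class": config.drug_class,
        "beta": beta.tolist(),
        "theta": config.theta,
        "alpha": config.alpha_vec().tolist(),
        "alpha_scale": config.alpha_scale,
        "causal_exposure_idx": np.flatnonzero(beta).tolist(),
        "direct_outcome_idx": np.flatnonzero(alpha).tolist(),
        "rsids": list(panel.rsids),
        "positions": positions.tolist(),
        "mafs": mafs.tolist(),
        "sigma_x": config.sigma_x,
        "n_x": config.n_x,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "rho": config.rho,
    }
    return exposure, outcome, panel, truth


def flip_outcome_alleles(outcome: SummaryDataset, rsids: list[str]) -> SummaryDataset:
    """Re-express the named outcome records on the opposite effect allele.

    The association content is unchanged; harmonization against the
    original exposure orientation must undo exactly these flips.
    """
    flipped = SummaryDataset(
        trait_name=outcome.trait_name,
        trait_type=outcome.trait_type,
        unit=outcome.unit,
        n_cases=outcome.n_cases,
        n_controls=outcome.n_controls,
    )
    targets = set(rsids)
    for rec in outcome:
        flipped.add(rec.flipped() if rec.rsid in targets else rec)
    return flipped


def _preset_configs(seed: int) -> dict[str, SimulationConfig]:
    base = dict(seed=seed, M=50, rho=0.5)
    M = 50
    # one strong causal variant in mid-region (~0.25% variance explained,
    # expected F = n beta^2/sigma^2 ~ 750 at biobank scale)
    one = _sparse(M, {25: 0.04})
    multi = _sparse(M, {5: 0.04, 25: 0.04, 45: 0.04})
    # 20 instruments, AR(1) lag 6 (r^2 = 0.5^12 < 0.001), graded strengths
    m_dir = 120
    dir_idx = list(range(0, 120, 6))
    dir_beta = _sparse(m_dir, {i: b for i, b in zip(dir_idx, np.linspace(0.008, 0.02, 20))})
    dir_alpha = _sparse(m_dir, {i: 0.05 for i in dir_idx})
    # 10 instruments, 4 of which carry a large positive direct effect
    m_bal = 60
    bal_idx = list(range(0, 60, 6))
    bal_beta = _sparse(m_bal, {i: 0.012 for i in bal_idx})
    bal_alpha = _sparse(m_bal, {i: 0.4 for i in bal_idx[:4]})
    # expected F ~ 1 + n beta^2 / sigma^2 = 8
    weak_beta = float(np.sqrt(7.0 * 0.8**2 / 309_895))
    return {
        "null-region": SimulationConfig(**base),
        "one-causal": SimulationConfig(**base, beta=one, theta=0.2),
        "multi-causal": SimulationConfig(**base, beta=multi, theta=0.2),
        "directional-pleiotropy": SimulationConfig(
            seed=seed, M=m_dir, rho=0.5, beta=dir_beta, alpha=dir_alpha, theta=0.2,
            alpha_scale="allelic",
        ),
        "balanced-pleiotropy": SimulationConfig(
            seed=seed, M=m_bal, rho=0.5, beta=bal_beta, alpha=bal_alpha, theta=0.2,
            alpha_scale="allelic",
        ),
        "weak-instrument": SimulationConfig(**base, beta=_sparse(M, {25: weak_beta}), theta=0.2),
        "shared-causal": SimulationConfig(**base, beta=_sparse(M, {25: 0.05}), theta=1.0),
        "distinct-causal": SimulationConfig(
            **base, beta=_sparse(M, {10: 0.05}), alpha=_sparse(M, {40: 0.1}), theta=0.0
        ),
    }


PRESETS = tuple(_preset_configs(0).keys())


def preset(name: str, seed: int, **overrides) -> SimulationConfig:
    """A named scenario config; ``overrides`` are applied last."""
    configs = _preset_configs(seed)
    if name not in configs:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(configs)}")
    cfg = configs[name]
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
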