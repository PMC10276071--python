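"""Cis-instrument selection for a drug target.

Variants are taken from the target gene region plus a flanking window
(default 2.5 kb), kept if their exposure association survives a
Benjamini–Hochberg FDR of 0.05 within the window, screened by the
palindromic-variant frequency rule, pruned by greedy LD clumping
(r² < 0.001 by default), and — when absent from the outcome dataset —
replaced by the best LD proxy with r² > 0.8.  Per-variant instrument
strength is the squared z statistic F = (beta/se)²; a mean F at or below
ten flags the set as weak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats import (
    DrugTarget,
    GwasRecord,
    LdReference,
    SummaryDataset,
    UnknownVariantError,
)

__all__ = [
    "SelectionParams",
    "SelectedInstrument",
    "InstrumentSet",
    "Exclusion",
    "extract_cis",
    "bh_fdr",
    "clump",
    "palindrome_admissible",
    "find_proxy",
    "f_statistic",
    "mean_f",
    "select_instruments",
]

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class SelectionParams:
    """Tunable thresholds of the instrument-selection pipeline."""

    window_bp: int = 2_500
    fdr_threshold: float = 0.05
    clump_r2: float = 0.001
    proxy_r2: float = 0.8
    palindrome_maf: float = 0.3
    proxy_flank_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        for name in ("fdr_threshold", "clump_r2", "proxy_r2", "palindrome_maf"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0,1], got {v}")


@dataclass(frozen=True)
class SelectedInstrument:
    """An exposure variant retained as an instrument."""

    record: GwasRecord
    qval: float
    f_stat: float
    proxy_of: str | None = None  # original instrument rsid when this is a proxy
    proxy_r2: float | None = None
    proxy_r_signed: float | None = None

    def __post_init__(self) -> None:
        if self.proxy_of is not None and (self.proxy_r2 is None or not self.proxy_r2 > 0.0):
            raise ValueError("proxy instruments must carry a positive proxy_r2")

    @property
    def rsid(self) -> str:
        return self.record.rsid


@dataclass(frozen=True)
class Exclusion:
    """One variant removed at one pipeline stage, with a reason code."""

    rsid: str
    stage: str
    reason: str


@dataclass
class InstrumentSet:
    """The instruments selected for one drug class."""

    drug_class: str
    instruments: list[SelectedInstrument]
    params: SelectionParams
    exclusions: list[Exclusion] = field(default_factory=list)

    @property
    def mean_f(self) -> float:
        if not self.instruments:
            return float("nan")
        return float(np.mean([ins.f_stat for ins in self.instruments]))

    @property
    def is_weak(self) -> bool:
        return len(self.instruments) > 0 and self.mean_f <= WEAK_F_THRESHOLD

    def __len__(self) -> int:
        return len(self.instruments)


def extract_cis(
    dataset: SummaryDataset, target: DrugTarget, window_bp: int = 2_500
) -> list[GwasRecord]:
    """Variants inside any target gene region ± window_bp (closed interval).

    Multi-gene targets take the union of windows; a variant falling in two
    overlapping windows is returned once.  Order follows the dataset.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    out: list[GwasRecord] = []
    for rec in dataset:
        for gene in target.genes:
            if rec.chrom == gene.chrom and (
                gene.start - window_bp <= rec.pos <= gene.end + window_bp
            ):
                out.append(rec)
                break
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the order statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def palindrome_admissible(record: GwasRecord, maf_cutoff: float = 0.3) -> bool:
    """Strand-ambiguity screen: palindromic (A/T, C/G) variants are admitted
    only when their minor allele frequency is below ``maf_cutoff``."""
    if not record.is_palindromic:
        return True
    return record.maf < maf_cutoff  # NaN maf (missing eaf) fails the test


def _clump_sort_key(rec: GwasRecord):
    # ties: ascending p, then position, then rsid — deterministic output
    return (rec.pval, rec.pos, rec.rsid)


def clump(
    records: list[GwasRecord],
    panel: LdReference,
    r2_threshold: float = 0.001,
    seed_rsids: list[str] | None = None,
) -> list[GwasRecord]:
    """Greedy LD clumping by ascending p-value.

    Retain the most significant remaining variant, discard everything with
    r² >= threshold against any retained one.  Output order is by the same
    deterministic key used for the greedy scan; the global minimum-p record
    is always retained, and pairwise r² among the output is < threshold.

    ``seed_rsids`` pre-populates the retained set (unconditionally) before
    the greedy scan.  A relaxed-threshold sensitivity run seeded with the
    strict run's output is therefore always a superset of it — pure greedy
    runs at two thresholds do not nest, because a variant discarded only at
    the relaxed threshold can shelter a later variant that the strict run
    discards.
    """
    for rec in records:
        if rec.rsid not in panel:
            raise UnknownVariantError(f"{rec.rsid} not in LD panel")
    seeds = set(seed_rsids or ())
    ordered = sorted(records, key=_clump_sort_key)
    retained: list[GwasRecord] = [r for r in ordered if r.rsid in seeds]
    for rec in ordered:
        if rec.rsid in seeds:
            continue
        if all(
            panel.r_signed(rec.rsid, kept.rsid) ** 2 < r2_threshold for kept in retained
        ):
            retained.append(rec)
    return sorted(retained, key=_clump_sort_key)


def find_proxy(
    rsid: str,
    outcome: SummaryDataset,
    panel: LdReference,
    r2_min: float = 0.8,
    candidate_rsids: list[str] | None = None,
    positions: dict[str, int] | None = None,
) -> tuple[str, float] | None:
    """Best LD proxy for an instrument missing from the outcome dataset.

    Scans panel variants present in the outcome (optionally restricted to
    ``candidate_rsids``) and returns ``(proxy_rsid, signed_r)`` for the
    maximal-r² candidate with r² > r2_min, or None when nothing qualifies.
    Ties in r² break by distance to the index variant (when positions are
    supplied) then by rsid.
    """
    if rsid not in panel:
        raise UnknownVariantError(f"{rsid} not in LD panel")
    if rsid in outcome:
        raise ValueError(f"{rsid} is present in the outcome dataset; no proxy needed")
    pool = candidate_rsids if candidate_rsids is not None else panel.rsids
    best: tuple[float, float, str, float] | None = None  # (-r2, dist, rsid, signed_r)
    for cand in pool:
        if cand == rsid or cand not in outcome or cand not in panel:
            continue
        r = panel.r_signed(rsid, cand)
        r2 = r * r
        if r2 <= r2_min:
            continue
        dist = 0.0
        if positions and rsid in positions and cand in positions:
            dist = abs(positions[cand] - positions[rsid])
        key = (-r2, dist, cand, r)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[3]


def f_statistic(record: GwasRecord) -> float:
    """Per-variant instrument strength F = (beta/se)²."""
    return (record.beta / record.se) ** 2


def mean_f(instruments: list[SelectedInstrument]) -> float:
    if not instruments:
        return float("nan")
    return float(np.mean([ins.f_stat for ins in instruments]))


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    target: DrugTarget,
    panel: LdReference,
    params: SelectionParams = SelectionParams(),
    forced_rsids: list[str] | None = None,
    clump_seed_rsids: list[str] | None = None,
) -> InstrumentSet:
    """Run the full cis-instrument selection pipeline for one drug class.

    Stages, in order: window extraction → BH-FDR filter (within the window)
    → palindrome screen → LD clumping → proxy lookup for variants absent
    from the outcome → per-variant F.  Every excluded variant is logged once
    with a stage and reason code.  An empty final set is a valid outcome
    ("no valid instruments"), not an error.

    ``forced_rsids`` bypasses the FDR ranking for functional variants of
    known biological relevance: those variants form the candidate set
    directly (they must still be cis, non-ambiguous, and present or
    proxyable in the outcome).
    """
    exclusions: list[Exclusion] = []
    cis = extract_cis(exposure, target, params.window_bp)

    if forced_rsids is not None:
        wanted = set(forced_rsids)
        candidates = [r for r in cis if r.rsid in wanted]
        missing = wanted - {r.rsid for r in candidates}
        for rsid in sorted(missing):
            exclusions.append(Exclusion(rsid, "forced", "not found in cis window"))
        qvals = {r.rsid: float("nan") for r in candidates}
    else:
        if cis:
            qv = bh_fdr([r.pval for r in cis])
            qvals = {r.rsid: float(q) for r, q in zip(cis, qv)}
            candidates = []
            for rec in cis:
                # a threshold of 1 disables the filter (q is capped at 1,
                # so a strict comparison would drop q == 1 variants)
                if params.fdr_threshold >= 1.0 or qvals[rec.rsid] < params.fdr_threshold:
                    candidates.append(rec)
                else:
                    exclusions.append(
                        Exclusion(rec.rsid, "fdr", f"q={qvals[rec.rsid]:.4g} >= {params.fdr_threshold}")
                    )
        else:
            candidates, qvals = [], {}

    admissible = []
    for rec in candidates:
        if palindrome_admissible(rec, params.palindrome_maf):
            admissible.append(rec)
        else:
            exclusions.append(
                Exclusion(rec.rsid, "palindrome", f"palindromic with maf >= {params.palindrome_maf}")
            )

    clumped = clump(admissible, panel, params.clump_r2, clump_seed_rsids)
    clumped_ids = {r.rsid for r in clumped}
    for rec in admissible:
        if rec.rsid not in clumped_ids:
            exclusions.append(Exclusion(rec.rsid, "clump", f"r2 >= {params.clump_r2} with a retained variant"))

    # proxy candidates: panel variants within the window plus flanks
    positions = {r.rsid: r.pos for r in exposure}
    flank_ids = [
        r.rsid
        for r in exposure
        if any(
            r.chrom == g.chrom
            and g.start - params.window_bp - params.proxy_flank_bp
            <= r.pos
            <= g.end + params.window_bp + params.proxy_flank_bp
            for g in target.genes
        )
        and r.rsid in panel
    ]

    instruments: list[SelectedInstrument] = []
    for rec in clumped:
        if rec.rsid in outcome:
            instruments.append(
                SelectedInstrument(rec, qvals.get(rec.rsid, float("nan")), f_statistic(rec))
            )
            continue
        hit = find_proxy(
            rec.rsid, outcome, panel, params.proxy_r2, candidate_rsids=flank_ids, positions=positions
        )
        if hit is None:
            exclusions.append(
                Exclusion(rec.rsid, "proxy", f"absent from outcome, no proxy with r2 > {params.proxy_r2}")
            )
            continue
        proxy_rsid, signed_r = hit
        proxy_rec = exposure[proxy_rsid] if proxy_rsid in exposure else None
        if proxy_rec is None:
            exclusions.append(
                Exclusion(rec.rsid, "proxy", f"proxy {proxy_rsid} missing exposure association")
            )
            continue
        if not palindrome_admissible(proxy_rec, params.palindrome_maf):
            exclusions.append(
                Exclusion(rec.rsid, "proxy", f"proxy {proxy_rsid} palindromic with high maf")
            )
            continue
        instruments.append(
            SelectedInstrument(
                proxy_rec,
                qvals.get(rec.rsid, float("nan")),
                f_statistic(proxy_rec),
                proxy_of=rec.rsid,
                proxy_r2=signed_r**2,
                proxy_r_signed=signed_r,
            )
        )

    return InstrumentSet(target.drug_class, instruments, params, exclusions)
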