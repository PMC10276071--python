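"""Core containers and I/O for GWAS summary statistics, LD panels and drug-target regions.

Summary statistics travel as a fixed 10-column tab-delimited layout
(``chrom pos rsid effect_allele other_allele eaf beta se pval n``) with a
mandatory header.  LD is a square signed-correlation matrix with an rsid
header row and column.  Drug-target regions come from a built-in table of
antidiabetic drug classes and the GRCh37 coordinates of the genes encoding
their target proteins, or from a user-supplied 5-column table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "SummaryDataset",
    "GeneRegion",
    "DrugTarget",
    "LdReference",
    "SumstatsFormatError",
    "UnknownVariantError",
    "UnknownTargetError",
    "read_sumstats",
    "write_sumstats",
    "load_drug_targets",
    "get_drug_target",
    "read_ld",
    "write_ld",
    "ld_r2",
]

_NUCLEOTIDES = frozenset("ACGT")

SUMSTATS_COLUMNS = (
    "chrom",
    "pos",
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


class SumstatsFormatError(ValueError):
    """Malformed summary-statistics, LD or target-region input."""


class UnknownVariantError(KeyError):
    """A variant id was not found in a dataset or LD panel."""


class UnknownTargetError(KeyError):
    """A drug class has no entry in the target-region table."""


@dataclass(frozen=True)
class GwasRecord:
    """One variant's association summary for one trait.

    ``beta`` is mmol/L per effect allele for continuous traits and log-odds
    per effect allele for binary traits; ``se`` is on the same scale.
    """

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.rsid}: alleles must be single nucleotides, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        # "." in the file maps to NaN: frequency unknown
        if not np.isnan(self.eaf) and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.rsid}: eaf must lie in (0,1), got {self.eaf}")
        if not self.se > 0.0:
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.rsid}: pval must lie in (0,1], got {self.pval}")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}

    def flipped(self) -> "GwasRecord":
        """The same association expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class SummaryDataset:
    """An ordered collection of :class:`GwasRecord` for one trait."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    unit: str = ""
    n_cases: int | None = None
    n_controls: int | None = None
    records: dict[str, GwasRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        if self.trait_type == "binary" and (self.n_cases is None or self.n_controls is None):
            raise ValueError("binary trait requires n_cases and n_controls")

    def add(self, rec: GwasRecord) -> None:
        if rec.rsid in self.records:
            raise ValueError(f"duplicate rsid {rec.rsid} in {self.trait_name}")
        self.records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> GwasRecord:
        try:
            return self.records[rsid]
        except KeyError:
            raise UnknownVariantError(f"{rsid} not in dataset {self.trait_name!r}") from None

    def __iter__(self):
        return iter(self.records.values())

    @property
    def case_fraction(self) -> float | None:
        if self.n_cases is None or self.n_controls is None:
            return None
        return self.n_cases / (self.n_cases + self.n_controls)


@dataclass(frozen=True)
class GeneRegion:
    """A gene's span on GRCh37, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SumstatsFormatError(
                f"{self.gene}: region start {self.start} exceeds end {self.end}"
            )


@dataclass(frozen=True)
class DrugTarget:
    """A drug class and the gene region(s) encoding its target protein(s)."""

    drug_class: str
    genes: tuple[GeneRegion, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.drug_class}: at least one gene region required")


# GRCh37 coordinates of the genes encoding each antidiabetic drug-target
# protein (DrugBank v5.0 / ChEMBL v29.0 consensus).  Metformin is excluded:
# the databases disagree on its target and its mechanism is unresolved.
_DRUG_TARGETS: tuple[DrugTarget, ...] = (
    DrugTarget("GLP-1 receptor agonists", (GeneRegion("GLP1R", "6", 39_016_557, 39_059_079),)),
    DrugTarget("SGLT2 inhibitors", (GeneRegion("SLC5A2", "16", 31_494_323, 31_502_181),)),
    DrugTarget("DPP-4 inhibitors", (GeneRegion("DPP4", "2", 162_848_755, 162_930_904),)),
    DrugTarget("Insulin and its analogues", (GeneRegion("INSR", "19", 7_112_266, 7_294_425),)),
    DrugTarget("Thiazolidinediones", (GeneRegion("PPARG", "3", 12_328_867, 12_475_855),)),
    DrugTarget(
        "Sulfonylureas",
        (
            GeneRegion("KCNJ11", "11", 17_386_719, 17_410_878),
            GeneRegion("ABCC8", "11", 17_414_045, 17_498_441),
        ),
    ),
)


def load_drug_targets(path: str | None = None) -> list[DrugTarget]:
    """Drug-target regions: the built-in antidiabetic table, or a user file.

    The user file is tab-delimited with columns
    ``chrom, start, end, gene, drug_class``; rows sharing a drug class are
    merged into one multi-gene target.
    """
    if path is None:
        return list(_DRUG_TARGETS)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gene", "drug_class"}
    missing = required - set(df.columns)
    if missing:
        raise SumstatsFormatError(f"target table missing column(s): {', '.join(sorted(missing))}")
    targets: dict[str, list[GeneRegion]] = {}
    for row in df.itertuples(index=False):
        region = GeneRegion(str(row.gene), str(row.chrom), int(row.start), int(row.end))
        targets.setdefault(str(row.drug_class), []).append(region)
    return [DrugTarget(name, tuple(regions)) for name, regions in targets.items()]


def get_drug_target(drug_class: str, targets: list[DrugTarget] | None = None) -> DrugTarget:
    """Look up one drug class by name (case-insensitive)."""
    pool = targets if targets is not None else list(_DRUG_TARGETS)
    for t in pool:
        if t.drug_class.lower() == drug_class.lower():
            return t
    raise UnknownTargetError(
        f"no target region for drug class {drug_class!r}; "
        f"known classes: {', '.join(t.drug_class for t in pool)}"
    )


def read_sumstats(
    path: str | io.TextIOBase,
    trait_name: str,
    trait_type: str = "continuous",
    unit: str = "",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryDataset:
    """Read the fixed 10-column tab-delimited summary-statistics layout.

    Every row is validated against the :class:`GwasRecord` invariants;
    violations raise :class:`SumstatsFormatError` naming the offending rsid.
    Row order is preserved.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "rsid": str},
        na_values=["."],
        float_precision="round_trip",
    )
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"summary statistics missing column(s): {', '.join(missing)}")
    ds = SummaryDataset(
        trait_name=trait_name,
        trait_type=trait_type,
        unit=unit,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    for row in df.itertuples(index=False):
        try:
            rec = GwasRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                rsid=str(row.rsid),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )
        except (ValueError, TypeError) as exc:
            raise SumstatsFormatError(f"invalid row for rsid {row.rsid!r}: {exc}") from exc
        ds.add(rec)
    return ds


def write_sumstats(ds: SummaryDataset, path: str | io.TextIOBase) -> None:
    """Write a dataset in the same layout :func:`read_sumstats` consumes.

    Floats use repr-round-tripping precision so write-then-read preserves
    values exactly.
    """
    df = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "rsid": r.rsid,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "." if np.isnan(r.eaf) else repr(r.eaf),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": repr(r.pval),
                "n": r.n,
            }
            for r in ds
        ],
        columns=list(SUMSTATS_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


class LdReference:
    """A signed correlation matrix r between variant allele dosages.

    The sign matters: proxy allele mapping uses it to decide whether the
    proxy's effect allele tracks the index variant's effect allele (r > 0)
    or its other allele (r < 0).
    """

    def __init__(self, rsids: list[str], r: np.ndarray, tol: float = 1e-8):
        r = np.asarray(r, dtype=float)
        m = len(rsids)
        if r.shape != (m, m):
            raise SumstatsFormatError(f"LD matrix shape {r.shape} does not match {m} rsids")
        if len(set(rsids)) != m:
            raise SumstatsFormatError("duplicate rsids in LD panel")
        if not np.allclose(r, r.T, atol=tol):
            raise SumstatsFormatError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=tol):
            raise SumstatsFormatError("LD matrix diagonal is not 1")
        if np.any(np.abs(r) > 1.0 + tol):
            raise SumstatsFormatError("LD matrix has |r| > 1")
        try:
            np.linalg.cholesky((r + r.T) / 2.0 + 2.0 * tol * np.eye(m))
        except np.linalg.LinAlgError:
            raise SumstatsFormatError("LD matrix not positive semidefinite") from None
        self.rsids = list(rsids)
        self.r = (r + r.T) / 2.0
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def __len__(self) -> int:
        return len(self.rsids)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise UnknownVariantError(f"{rsid} not in LD panel") from None

    def r_signed(self, rsid_a: str, rsid_b: str) -> float:
        return float(self.r[self.index(rsid_a), self.index(rsid_b)])


def ld_r2(panel: LdReference, rsid_a: str, rsid_b: str) -> float:
    """Squared correlation between two panel variants (symmetric in arguments)."""
    return panel.r_signed(rsid_a, rsid_b) ** 2


def read_ld(path: str | io.TextIOBase) -> LdReference:
    """Read a square LD matrix with an rsid header row and rsid first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise SumstatsFormatError("LD matrix header row and column disagree")
    return LdReference([str(x) for x in df.columns], df.to_numpy(dtype=float))


def write_ld(panel: LdReference, path: str | io.TextIOBase) -> None:
    df = pd.DataFrame(panel.r, index=panel.rsids, columns=panel.rsids)
    df.to_csv(path, sep="\t", float_format="%.12g")
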