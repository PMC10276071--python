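"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs both effect estimates expressed per copy of the same
allele.  The outcome record is re-oriented to the exposure's effect allele:
a swapped allele pair negates the outcome beta and complements its
frequency; strand complements (A/G vs T/C reported on opposite strands) are
resolved before declaring incompatibility; palindromic pairs, where strand
cannot be inferred from the alleles, are aligned by allele-frequency
concordance and dropped when both frequencies are too close to 0.5 to
adjudicate.  Proxy pairs are mapped through the sign of the panel LD
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .selection import Exclusion, InstrumentSet, SelectedInstrument
from .sumstats import GwasRecord, LdReference, SummaryDataset

__all__ = ["HarmonizedInstrument", "HarmonizationError", "harmonize_pair", "align_datasets"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# both frequencies inside this band ⇒ palindromic orientation unresolvable
AMBIGUITY_BAND = (0.42, 0.58)


class HarmonizationError(ValueError):
    """Allele configurations that cannot be reconciled."""


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An instrument with exposure and outcome effects on a shared allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float
    eaf_y: float
    flipped: bool = False
    proxy_of: str | None = None
    proxy_r2: float | None = None

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.rsid}: standard errors must be positive")


def _in_band(f: float) -> bool:
    lo, hi = AMBIGUITY_BAND
    return lo < f < hi


def harmonize_pair(
    exposure: GwasRecord,
    outcome: GwasRecord,
    signed_proxy_r: float | None = None,
    proxy_of: str | None = None,
    proxy_r2: float | None = None,
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure's effect allele.

    ``signed_proxy_r`` handles proxy pairs (different rsids): allele letters
    are not comparable across distinct variants, so the panel correlation's
    sign is the only alignment information — negative r means the proxy's
    effect allele (in the panel's recorded orientation, assumed to match the
    outcome file's) tracks the index variant's *other* allele, so the
    proxy's effect and frequency are flipped.  The harmonized record carries
    the index variant's alleles.
    """
    ea, oa = exposure.effect_allele, exposure.other_allele

    if signed_proxy_r is not None and outcome.rsid != exposure.rsid:
        out = outcome.flipped() if signed_proxy_r < 0 else outcome
        return HarmonizedInstrument(
            rsid=exposure.rsid,
            effect_allele=ea,
            other_allele=oa,
            beta_x=exposure.beta,
            se_x=exposure.se,
            beta_y=out.beta,
            se_y=out.se,
            eaf_x=exposure.eaf,
            eaf_y=out.eaf,
            flipped=signed_proxy_r < 0,
            proxy_of=proxy_of if proxy_of is not None else outcome.rsid,
            proxy_r2=proxy_r2 if proxy_r2 is not None else signed_proxy_r**2,
        )

    out = outcome
    flipped = False

    if exposure.is_palindromic:
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            raise HarmonizationError(
                f"{exposure.rsid}: outcome alleles {out.effect_allele}/{out.other_allele} "
                f"incompatible with palindromic exposure {ea}/{oa}"
            )
        # For a palindromic pair "swap" and "strand complement" are
        # indistinguishable from the alleles alone; orient by frequency.
        if _in_band(exposure.eaf) and _in_band(out.eaf):
            raise HarmonizationError(
                f"{exposure.rsid}: palindromic with both frequencies near 0.5; "
                "orientation unresolvable"
            )
        aligned = out if out.effect_allele == ea else out.flipped()
        concordant = abs(exposure.eaf - aligned.eaf) <= abs(exposure.eaf - (1.0 - aligned.eaf))
        if not concordant:
            aligned = aligned.flipped()
        flipped = aligned.beta != outcome.beta or aligned.effect_allele != outcome.effect_allele
        out = aligned
    else:
        if (out.effect_allele, out.other_allele) == (ea, oa):
            pass
        elif (out.effect_allele, out.other_allele) == (oa, ea):
            out = out.flipped()
            flipped = True
        else:
            comp = (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele])
            if comp == (ea, oa):
                pass  # same orientation, opposite strand
            elif comp == (oa, ea):
                out = out.flipped()
                flipped = True
            else:
                raise HarmonizationError(
                    f"{exposure.rsid}: outcome alleles {outcome.effect_allele}/"
                    f"{outcome.other_allele} incompatible with exposure {ea}/{oa}"
                )

    return HarmonizedInstrument(
        rsid=exposure.rsid,
        effect_allele=ea,
        other_allele=oa,
        beta_x=exposure.beta,
        se_x=exposure.se,
        beta_y=out.beta,
        se_y=out.se,
        eaf_x=exposure.eaf,
        eaf_y=out.eaf,
        flipped=flipped,
        proxy_of=proxy_of,
        proxy_r2=proxy_r2,
    )


def align_datasets(
    instruments: InstrumentSet,
    outcome: SummaryDataset,
    panel: LdReference | None = None,
) -> tuple[list[HarmonizedInstrument], list[Exclusion]]:
    """Harmonize every selected instrument against the outcome dataset.

    Returns the surviving harmonized instruments and the per-variant drops
    (outcome record missing, or alleles irreconcilable).
    """
    out: list[HarmonizedInstrument] = []
    drops: list[Exclusion] = []
    for ins in instruments.instruments:
        rsid = ins.rsid
        if rsid not in outcome:
            drops.append(Exclusion(rsid, "harmonize", "absent from outcome dataset"))
            continue
        try:
            # Proxy substitution already happened at selection: both records
            # here describe the proxy variant itself, so no sign mapping.
            h = harmonize_pair(
                ins.record,
                outcome[rsid],
                proxy_of=ins.proxy_of,
                proxy_r2=ins.proxy_r2,
            )
        except HarmonizationError as exc:
            drops.append(Exclusion(rsid, "harmonize", str(exc)))
            continue
        out.append(h)
    return out, drops
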