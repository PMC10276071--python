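import numpy as np
import pytest

from targetmr import GwasRecord, LdReference, SummaryDataset


def make_record(
    rsid="rs1",
    chrom="3",
    pos=12_400_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.02,
    se=0.005,
    pval=1e-4,
    n=300_000,
):
    return GwasRecord(
        chrom=chrom,
        pos=pos,
        rsid=rsid,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_dataset(records, name="trait", trait_type="continuous", **kw):
    ds = SummaryDataset(trait_name=name, trait_type=trait_type, **kw)
    for r in records:
        ds.add(r)
    return ds


@pytest.fixture
def ar1_panel():
    """5-variant AR(1) panel, rho = 0.5, rsids rs1..rs5."""
    idx = np.arange(5)
    r = 0.5 ** np.abs(idx[:, None] - idx[None, :])
    return LdReference([f"rs{i + 1}" for i in range(5)], r)
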