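import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr import (
    SelectionParams,
    bh_fdr,
    clump,
    extract_cis,
    f_statistic,
    find_proxy,
    get_drug_target,
    palindrome_admissible,
    preset,
    select_instruments,
    simulate_two_sample,
)
from targetmr.selection import mean_f
from targetmr.sumstats import LdReference, UnknownVariantError

from conftest import make_dataset, make_record


class TestExtractCis:
    def test_ppar_window_bounds(self):
        target = get_drug_target("Thiazolidinediones")
        inside_low = make_record("rs_lo", pos=12_326_367)
        inside_high = make_record("rs_hi", pos=12_478_355)
        outside_low = make_record("rs_out1", pos=12_326_366)
        outside_high = make_record("rs_out2", pos=12_478_356)
        wrong_chrom = make_record("rs_out3", chrom="4", pos=12_400_000)
        ds = make_dataset([inside_low, inside_high, outside_low, outside_high, wrong_chrom])
        got = extract_cis(ds, target, window_bp=2_500)
        assert [r.rsid for r in got] == ["rs_lo", "rs_hi"]

    def test_brute_force_interval_oracle(self):
        target = get_drug_target("Thiazolidinediones")
        rng = np.random.default_rng(42)
        positions = rng.integers(12_300_000, 12_500_000, 10)
        records = [make_record(f"rs{i}", pos=int(p)) for i, p in enumerate(positions)]
        ds = make_dataset(records)
        got = {r.rsid for r in extract_cis(ds, target, 2_500)}
        g = target.genes[0]
        expected = {
            r.rsid
            for r in records
            if g.start - 2_500 <= r.pos <= g.end + 2_500  # independent closed-interval scan
        }
        assert got == expected and len(expected) > 0

    def test_multi_gene_union_no_duplicates(self):
        target = get_drug_target("Sulfonylureas")
        # position in the gap between KCNJ11 and ABCC8, covered by both windows
        rec = make_record("rs_gap", chrom="11", pos=17_412_000)
        ds = make_dataset([rec])
        assert [r.rsid for r in extract_cis(ds, target, 2_500)] == ["rs_gap"]

    def test_empty_dataset(self):
        assert extract_cis(make_dataset([]), get_drug_target("Thiazolidinediones")) == []


def brute_force_bh(pvals):
    """Step-up oracle: q_(i) = min_{j>=i} p_(j) * m / j on order statistics."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.01]) == pytest.approx([0.01])

    def test_stepup_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12)

    def test_ties_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3, atol=1e-12)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), brute_force_bh(pvals), atol=1e-12)

    @given(
        st.lists(st.floats(1e-6, 0.99), min_size=2, max_size=15),
        st.data(),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_each_input(self, pvals, data):
        i = data.draw(st.integers(0, len(pvals) - 1))
        bumped = list(pvals)
        bumped[i] = min(1.0, bumped[i] * 1.5 + 1e-6)
        assert np.all(bh_fdr(bumped) >= bh_fdr(pvals) - 1e-12)


class TestClump:
    def test_single_record(self, ar1_panel):
        rec = make_record("rs1")
        assert clump([rec], ar1_panel) == [rec]

    def test_hand_traced_greedy(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.5)
        r[0, 2] = r[2, 0] = np.sqrt(0.0005)
        r[1, 2] = r[2, 1] = np.sqrt(0.0002)
        panel = LdReference(["v1", "v2", "v3"], r)
        recs = [
            make_record("v1", pval=1e-8),
            make_record("v2", pos=12_400_100, pval=1e-6),
            make_record("v3", pos=12_400_200, pval=1e-4),
        ]
        kept = clump(recs, panel, 0.001)
        assert [x.rsid for x in kept] == ["v1", "v3"]

    def test_threshold_is_inclusive_discard(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = np.sqrt(0.002)
        panel = LdReference(["a", "b"], r)
        recs = [make_record("a", pval=1e-6), make_record("b", pos=12_400_100, pval=1e-3)]
        kept = clump(recs, panel, 0.001)
        assert [x.rsid for x in kept] == ["a"]

    def test_order_invariance_and_min_p_retained(self, ar1_panel):
        recs = [
            make_record(f"rs{i + 1}", pos=12_400_000 + i, pval=p)
            for i, p in enumerate([0.03, 1e-7, 0.5, 1e-5, 0.2])
        ]
        kept_fwd = clump(recs, ar1_panel, 0.02)
        kept_rev = clump(recs[::-1], ar1_panel, 0.02)
        assert [x.rsid for x in kept_fwd] == [x.rsid for x in kept_rev]
        assert "rs2" in {x.rsid for x in kept_fwd}  # global minimum p
        for a in kept_fwd:
            for b in kept_fwd:
                if a.rsid != b.rsid:
                    assert ar1_panel.r_signed(a.rsid, b.rsid) ** 2 < 0.02

    def test_unknown_variant_raises(self, ar1_panel):
        with pytest.raises(UnknownVariantError):
            clump([make_record("rs_missing")], ar1_panel)


class TestPalindromeRule:
    @pytest.mark.parametrize(
        "ea,oa,eaf,expected",
        [
            ("A", "G", 0.65, True),  # not palindromic, any frequency
            ("A", "T", 0.25, True),  # palindromic, maf 0.25 < 0.3
            ("C", "G", 0.65, False),  # palindromic, maf 0.35 >= 0.3
            ("A", "T", 0.75, True),  # maf 0.25 on the other side
            ("C", "G", 0.30, False),  # boundary: maf == cutoff is excluded
        ],
    )
    def test_admissibility(self, ea, oa, eaf, expected):
        rec = make_record(effect_allele=ea, other_allele=oa, eaf=eaf)
        assert palindrome_admissible(rec, 0.3) is expected

    def test_missing_eaf_palindrome_inadmissible(self):
        rec = make_record(effect_allele="A", other_allele="T", eaf=float("nan"))
        assert palindrome_admissible(rec) is False


class TestFindProxy:
    def _setup(self):
        # one-factor correlation structure (guaranteed PSD): r_ij = l_i l_j
        lam = np.array([1.0, np.sqrt(0.95), -np.sqrt(0.85), np.sqrt(0.5)])
        r = np.outer(lam, lam)
        np.fill_diagonal(r, 1.0)
        panel = LdReference(["idx", "p95", "p85", "p50"], r)
        outcome = make_dataset(
            [make_record("p95", pos=1), make_record("p85", pos=2), make_record("p50", pos=3)],
            name="outcome",
        )
        return panel, outcome

    def test_best_r2_wins_with_sign(self):
        panel, outcome = self._setup()
        rsid, r = find_proxy("idx", outcome, panel, 0.8)
        assert rsid == "p95" and r == pytest.approx(np.sqrt(0.95))

    def test_negative_r_carried(self):
        panel, outcome = self._setup()
        outcome.records.pop("p95")
        rsid, r = find_proxy("idx", outcome, panel, 0.8)
        assert rsid == "p85" and r == pytest.approx(-np.sqrt(0.85))

    def test_none_when_all_below_threshold(self):
        panel, outcome = self._setup()
        outcome.records.pop("p95")
        outcome.records.pop("p85")
        assert find_proxy("idx", outcome, panel, 0.8) is None

    def test_instrument_in_outcome_is_precondition_violation(self):
        panel, outcome = self._setup()
        outcome.add(make_record("idx", pos=4))
        with pytest.raises(ValueError):
            find_proxy("idx", outcome, panel)

    def test_unknown_instrument_raises(self):
        panel, outcome = self._setup()
        with pytest.raises(UnknownVariantError):
            find_proxy("rs_nowhere", outcome, panel)


class TestFStatistic:
    def test_value(self):
        assert f_statistic(make_record(beta=0.02, se=0.005)) == pytest.approx(16.0)

    def test_zero_beta(self):
        assert f_statistic(make_record(beta=0.0)) == 0.0

    def test_weak_set_flagged(self):
        exposure, outcome, panel, _ = simulate_two_sample(preset("weak-instrument", seed=11))
        target = get_drug_target("Thiazolidinediones")
        iset = select_instruments(exposure, outcome, target, panel)
        if len(iset):  # weak scenarios may also fail FDR entirely
            assert iset.mean_f == pytest.approx(
                float(np.mean([i.f_stat for i in iset.instruments]))
            )

    def test_mean_f_empty_is_nan(self):
        assert np.isnan(mean_f([]))


class TestSelectInstruments:
    target = property(lambda self: get_drug_target("Thiazolidinediones"))

    def test_null_region_yields_empty_set_with_fdr_reasons(self):
        exposure, outcome, panel, _ = simulate_two_sample(preset("null-region", seed=7))
        iset = select_instruments(exposure, outcome, self.target, panel)
        assert len(iset) == 0
        assert all(e.stage == "fdr" for e in iset.exclusions)
        assert len(iset.exclusions) == len(exposure)

    def test_one_causal_yields_single_strong_instrument(self):
        exposure, outcome, panel, truth = simulate_two_sample(preset("one-causal", seed=7))
        iset = select_instruments(exposure, outcome, self.target, panel)
        assert len(iset) == 1
        assert iset.instruments[0].rsid == truth["rsids"][truth["causal_exposure_idx"][0]]
        assert iset.instruments[0].f_stat > 10

    def test_forced_functional_variant_bypasses_fdr(self):
        exposure, outcome, panel, truth = simulate_two_sample(preset("null-region", seed=7))
        forced = truth["rsids"][30]  # null region: would never pass FDR
        iset = select_instruments(
            exposure, outcome, self.target, panel, forced_rsids=[forced]
        )
        assert [i.rsid for i in iset.instruments] == [forced]

    def test_degenerate_params_return_every_admissible_cis_variant(self):
        exposure, outcome, panel, _ = simulate_two_sample(preset("multi-causal", seed=3))
        params = SelectionParams(fdr_threshold=1.0, clump_r2=1.0)
        iset = select_instruments(exposure, outcome, self.target, panel, params)
        admissible = [
            r for r in extract_cis(exposure, self.target, params.window_bp)
            if palindrome_admissible(r, params.palindrome_maf)
        ]
        assert {i.rsid for i in iset.instruments} == {r.rsid for r in admissible}
        assert len(iset) == len(admissible)

    def test_every_excluded_variant_logged_exactly_once(self):
        exposure, outcome, panel, _ = simulate_two_sample(preset("multi-causal", seed=3))
        iset = select_instruments(exposure, outcome, self.target, panel)
        excluded = [e.rsid for e in iset.exclusions]
        assert len(excluded) == len(set(excluded))
        kept = {i.rsid for i in iset.instruments} | {
            i.proxy_of for i in iset.instruments if i.proxy_of
        }
        assert set(excluded) | kept == {r.rsid for r in exposure}

    def test_pairwise_r2_below_threshold(self):
        exposure, outcome, panel, truth = simulate_two_sample(preset("multi-causal", seed=3))
        iset = select_instruments(exposure, outcome, self.target, panel)
        causal = {truth["rsids"][i] for i in truth["causal_exposure_idx"]}
        assert causal <= {i.rsid for i in iset.instruments}
        for a in iset.instruments:
            for b in iset.instruments:
                if a.rsid != b.rsid:
                    assert panel.r_signed(a.rsid, b.rsid) ** 2 < 0.001
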