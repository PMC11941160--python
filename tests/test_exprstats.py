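import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from yeastfish import presets
from yeastfish.exceptions import UndefinedStatisticError
from yeastfish.exprstats import (
    bud_enrichment,
    compensation_report,
    letter_values,
    mw_test,
    pearson_pair,
    phase_resolved,
    summarize,
)
from yeastfish.simcounts import COUNT_COLUMNS, simulate_counts, make_strain


def make_table(counts, gene="G", strain="WT", phase="G1", compartment="whole"):
    return pd.DataFrame(
        [
            (i + 1, "e", strain, phase, compartment, gene, c)
            for i, c in enumerate(counts)
        ],
        columns=COUNT_COLUMNS,
    )


class TestSummarize:
    def test_basic_sample(self):
        s = summarize([0, 0, 1, 3])
        assert s.mean == 1.0 and s.zero_fraction == 0.5 and s.max_count == 3

    def test_all_zeros(self):
        s = summarize([0] * 20)
        assert s.zero_fraction == 1.0
        assert all(lv.lower == 0 and lv.upper == 0 for lv in s.letter_values)

    def test_letter_values_match_quantile_oracle(self, rng):
        x = np.sort(rng.gamma(2.0, 3.0, 10_000))
        n = len(x)
        for lv in letter_values(x):
            d = lv.depth
            lo = 0.5 * (x[int(np.floor(d)) - 1] + x[int(np.ceil(d)) - 1])
            hi = 0.5 * (x[n - int(np.floor(d))] + x[n - int(np.ceil(d))])
            assert lv.lower == pytest.approx(lo)
            assert lv.upper == pytest.approx(hi)

    def test_letter_values_weakly_increasing(self, rng):
        lvs = letter_values(rng.poisson(2, 501))
        ordered = [lv.lower for lv in reversed(lvs)] + [lv.upper for lv in lvs]
        assert all(a <= b for a, b in zip(ordered, ordered[1:]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize([])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_pair(x, x).statistic == pytest.approx(1.0)
        assert pearson_pair(x, -x + 3).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 1.0, 3.0, 5.0])
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson_pair(x, y).statistic == pytest.approx(r_direct, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_pair([1, 1, 1, 1], [1, 2, 3, 4])


def brute_force_mw_p(a, b, alternative="two-sided"):
    """Enumeration oracle: U distribution over all rank assignments."""
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.array(us)
    p_le = (us <= u_obs + 1e-9).mean()
    p_ge = (us >= u_obs - 1e-9).mean()
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = mw_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 20)
        assert res.method == "mann-whitney-exact"

    def test_identical_groups_u_half(self):
        res = mw_test([5, 6, 7, 8], [5, 6, 7, 8])
        assert res.statistic == pytest.approx(4 * 4 / 2)

    def test_exact_branch_equals_enumeration(self, rng):
        for _ in range(60):
            n1 = rng.integers(2, 6)
            n2 = rng.integers(2, 11 - n1)
            a = rng.permutation(100)[: n1 + n2]  # distinct values, no ties
            x, y = a[:n1].astype(float), a[n1:].astype(float)
            res = mw_test(x, y)
            assert res.method == "mann-whitney-exact"
            assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_tie_branch_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, 30).astype(float)
            b = rng.integers(0, 5, 25).astype(float)
            res = mw_test(a, b)
            sp = ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert res.statistic == pytest.approx(sp.statistic)
            assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=5),
        st.lists(st.integers(1001, 2000), min_size=2, max_size=5),
    )
    @settings(max_examples=25, deadline=None)
    def test_exact_p_in_unit_interval(self, a, b):
        res = mw_test(a, b)
        assert 0.0 <= res.p_value <= 1.0
        assert 0 <= res.statistic <= len(a) * len(b)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mw_test([], [1, 2])


class TestPhaseResolved:
    def test_single_phase_equals_summarize(self):
        t = make_table([0, 1, 2, 3], phase="G1")
        out = phase_resolved(t, "G")
        s, arr = out["G1"]
        assert s.mean == 1.5 and len(arr) == 4

    def test_g2_peak_recovered_from_generator(self):
        g = presets.study_gene("CLB1")  # G2-peaked profile
        t = simulate_counts([g], n_cells=8000, seed=13)
        out = phase_resolved(t, "CLB1")
        means = {ph: s.mean for ph, (s, _) in out.items() if s is not None}
        assert max(means, key=means.get) == "G2"

    def test_row_order_invariance(self):
        t = make_table(list(range(10)))
        shuffled = t.sample(frac=1.0, random_state=1)
        a = phase_resolved(t, "G")
        b = phase_resolved(shuffled, "G")
        np.testing.assert_array_equal(a["G1"][1], b["G1"][1])

    def test_unknown_phase_raises(self):
        t = make_table([1, 2], phase="weird")
        with pytest.raises(ValueError):
            phase_resolved(t, "G")


class TestBudEnrichment:
    @staticmethod
    def _pair_table(mother, bud):
        rows = []
        for i, (m, b) in enumerate(zip(mother, bud), start=1):
            rows.append((i, "e", "WT", "G2", "mother", "G", m))
            rows.append((i, "e", "WT", "G2", "bud", "G", b))
            rows.append((i, "e", "WT", "G2", "whole", "G", m + b))
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)

    def test_extreme_and_even_fractions(self):
        rep = bud_enrichment(self._pair_table([0, 2], [5, 2]), "G")
        assert rep.per_pair["bud_fraction"].tolist() == [1.0, 0.5]

    def test_generator_bud_transport_recovered(self):
        from yeastfish.simcounts import GeneModel

        g = GeneModel("G", mu_by_phase=4.0, burst_size=2.0)
        strain = make_strain("WT", bud_transport={"G": 0.8})
        t = simulate_counts([g], strain=strain, n_cells=12000, seed=14)
        rep = bud_enrichment(t, "G")
        assert rep.n_pairs > 3000
        assert rep.mean_bud_fraction == pytest.approx(0.8, abs=0.02)

    def test_no_pairs_empty_report(self):
        t = make_table([1, 2, 3])  # whole rows only
        rep = bud_enrichment(t, "G")
        assert rep.n_pairs == 0


class TestCompensationReport:
    def test_printed_summary_inputs_exact(self):
        wt = make_table([0] * 68 + [3] * 16 + [2] * 16, strain="WT")
        dl = make_table([0] * 27 + [6] * 15 + [5] * 58, strain="clb2D")
        rep = compensation_report(wt, dl, "G", "CLB2")
        assert rep.delta_zero_fraction == pytest.approx(-0.41, abs=1e-12)
        assert rep.mean_fold_change == pytest.approx(4.75, abs=1e-12)
        assert rep.verdict

    def test_identical_tables_no_verdict(self):
        t = make_table([0, 1, 2, 0, 4] * 10)
        rep = compensation_report(t, t.copy(), "G")
        assert rep.delta_zero_fraction == 0.0
        assert rep.mean_fold_change == pytest.approx(1.0)
        assert not rep.verdict

    def test_generator_scenarios_match_verdict_pattern(self):
        genes = [presets.study_gene("CLB1"), presets.study_gene("CLB2")]
        wt = simulate_counts(genes, strain=presets.wild_type(), n_cells=6000, seed=15)
        compensated = simulate_counts(
            genes, strain=presets.deletion_strain("clb2D"), n_cells=6000, seed=16
        )
        neutral = simulate_counts(
            genes,
            strain=make_strain("clb2D_neutral", deleted=["CLB2"]),
            n_cells=6000,
            seed=17,
        )
        assert compensation_report(wt, compensated, "CLB1").verdict
        assert not compensation_report(wt, neutral, "CLB1").verdict

    def test_missing_gene_raises(self):
        t = make_table([1, 2])
        with pytest.raises(ValueError):
            compensation_report(t, t, "NOPE")
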