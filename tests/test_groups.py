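"""Group comparison protocol: rank tests, Dunn post-hoc, cohort summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosocial.groups import (
    benjamini_hochberg,
    compare_multi,
    compare_statistic,
    compare_two,
    summarize_cohort,
)
from mitosocial.simulate import SimulationConfig, make_cohort


def exact_rank_sum_p(a, b):
    """Enumeration oracle: exact two-sided rank-sum p-value (no ties)."""
    pooled = sorted(a + b)
    ranks_a = [pooled.index(v) + 1 for v in a]
    observed = sum(ranks_a)
    n, m = len(a), len(b)
    all_ranks = range(1, n + m + 1)
    sums = [sum(c) for c in itertools.combinations(all_ranks, n)]
    mean = n * (n + m + 1) / 2
    dev = abs(observed - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


class TestCompareTwo:
    def test_identical_groups_p_one(self):
        res = compare_two({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.p_value == pytest.approx(1.0)
        assert res.test == "wilcoxon_rank_sum"

    def test_fully_separated_groups_exact_p(self):
        a, b = [1, 2, 3, 4], [10, 11, 12, 13]
        res = compare_two({"a": a, "b": b})
        assert res.method == "exact"
        # U = 0 for the low group; 2/C(8,4) = 2/70 by enumeration
        assert res.statistic in (0.0, 16.0)
        assert res.p_value == pytest.approx(2 / 70, abs=1e-12)
        assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(20)[:9].tolist()  # distinct -> tie-free
        a, b = [float(v) for v in vals[:4]], [float(v) for v in vals[4:]]
        res = compare_two({"a": a, "b": b})
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)

    def test_ties_or_large_n_use_asymptotic(self):
        res = compare_two({"a": [1, 1, 2], "b": [2, 3, 3]})
        assert res.method == "asymptotic"
        big = list(range(15)), list(range(15, 30))
        assert compare_two(big).method == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_two({"a": [], "b": [1.0]})

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 12).tolist()
        b = rng.normal(0.8, 1, 14).tolist()
        p1 = compare_two({"a": a, "b": b}).p_value
        f = lambda xs: [math.exp(x) for x in xs]  # strictly increasing
        p2 = compare_two({"a": f(a), "b": f(b)}).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_power_under_two_sd_shift(self):
        # per-cell summaries shifted by 2 SD, n=20/20: the rank-sum test
        # should reject at 5% in the vast majority of replicates
        rng = np.random.default_rng(21)
        hits = sum(
            compare_two(
                {"a": rng.normal(0, 1, 20), "b": rng.normal(2, 1, 20)}
            ).p_value
            < 0.05
            for _ in range(200)
        )
        assert hits >= 180


class TestCompareMulti:
    def test_three_identical_groups(self):
        res = compare_multi({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_ranked_example_h(self):
        # groups {1..3},{4..6},{7..9}: mean ranks 2, 5, 8 ->
        # H = 12/(9·10)·3·(4+25+64) − 3·10 = 7.2
        res = compare_multi({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.test == "kruskal_wallis"
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_dunn_z_matches_hand_computation(self):
        # tie-free, equal n: se = sqrt((N(N+1)/12)(1/3+1/3)) = sqrt(5/3·... )
        res = compare_multi({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        se = math.sqrt((9 * 10 / 12) * (2 / 3))
        row = res.posthoc.set_index(["group_a", "group_b"])
        assert row.loc[("a", "b"), "z"] == pytest.approx((2 - 5) / se, abs=1e-12)
        assert row.loc[("a", "c"), "z"] == pytest.approx((2 - 8) / se, abs=1e-12)

    def test_dunn_symmetric_in_group_order(self):
        g1 = {"a": [1.0, 4.0], "b": [2.0, 5.0], "c": [9.0, 10.0]}
        g2 = {"c": g1["c"], "b": g1["b"], "a": g1["a"]}
        r1 = compare_multi(g1).posthoc
        r2 = compare_multi(g2).posthoc

        def zmap(t):
            return {
                frozenset((ra.group_a, ra.group_b)): abs(ra.z) for ra in t.itertuples()
            }

        z1, z2 = zmap(r1), zmap(r2)
        assert z1.keys() == z2.keys()
        for k in z1:
            assert z1[k] == pytest.approx(z2[k], abs=1e-12)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abcd")}
        tab = compare_multi(groups).posthoc
        assert (tab["p_adjusted"] >= tab["p_raw"] - 1e-15).all()
        assert (tab["p_adjusted"] <= 1.0).all()

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="compare_two"):
            compare_multi({"a": [1.0], "b": [2.0]})


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
def test_bh_adjustment_properties(seed, n):
    """BH: order-preserving, >= raw, <= 1, and monotone after sorting."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, n)
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-15).all()
    assert (adj <= 1.0 + 1e-15).all()
    order = np.argsort(p)
    sorted_adj = adj[order]
    assert (np.diff(sorted_adj) >= -1e-15).all()


@pytest.fixture(scope="module")
def small_cohort():
    base = SimulationConfig(n_mito=15, n_frames=20)
    return make_cohort(base, {"wt": {}, "mut": {}}, 3, seed=17)


class TestSummarizeCohort:
    def test_shape_one_row_per_cell_statistic_checkpoint(self, small_cohort):
        table = summarize_cohort(small_cohort)
        per_stat = table.groupby("statistic")["cell_id"].nunique()
        assert (per_stat == 6).all()
        # physical stats: full window only; network stats: 4 checkpoints
        eff = table[table["statistic"] == "efficiency"]
        assert eff.groupby("cell_id").size().eq(4).all()
        imd = table[table["statistic"] == "mean_intermito_distance_um"]
        assert imd.groupby("cell_id").size().eq(1).all()

    def test_rerun_identical(self, small_cohort):
        t1 = summarize_cohort(small_cohort)
        t2 = summarize_cohort(small_cohort)
        assert t1.equals(t2)

    def test_compare_statistic_dispatch(self, small_cohort):
        table = summarize_cohort(small_cohort)
        res = compare_statistic(table, "mean_degree")
        assert res.test == "wilcoxon_rank_sum"
        assert set(res.groups) == {"wt", "mut"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([])
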