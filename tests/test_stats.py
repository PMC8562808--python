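"""Objectives, percentile measure, and nonparametric battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from trailnets.core import DayRecord, observed_network
from trailnets.stats import (
    ObjectiveVector,
    aggregate_percentiles,
    comparison_differences,
    compute_objectives,
    conover_iman,
    friedman,
    objective_correlations,
    percentile,
    wilcoxon_paired,
)

from conftest import build_map


class TestComputeObjectives:
    def test_lengths_and_totals(self):
        days = [DayRecord(1, frozenset({"a"}), frozenset({"e1", "e2", "e3"}))]
        m = build_map(
            {
                "e1": ("a", "b", 10.0),
                "e2": ("b", "c", 20.0),
                "e3": ("c", "d", 30.0),
            },
            root="a",
            days=days,
        )
        ov = compute_objectives(observed_network(m, 1), m)
        assert ov.avg_edge_length == pytest.approx(20.0)
        assert ov.total_length == pytest.approx(60.0)
        assert ov.total_nodes == 4

    def test_avg_ti_over_outbound_transitions(self):
        days = [DayRecord(1, frozenset({"a"}), frozenset({"e1", "e2", "e3"}))]
        m = build_map(
            {
                "e1": ("a", "b", 1.0),
                "e2": ("b", "c", 1.0),
                "e3": ("c", "d", 1.0),
            },
            root="a",
            days=days,
            transitions={("e1", "b", "e2"): 1, ("e2", "c", "e3"): 4},
            default_ti=1,
        )
        ov = compute_objectives(observed_network(m, 1), m)
        assert ov.avg_ti == pytest.approx(2.5)  # mean of TI 1 and 4

    def test_single_node_network_mostly_missing(self):
        from trailnets.core import TrailNetwork

        m = build_map({"e1": ("a", "b", 1.0), "e2": ("b", "c", 1.0)}, root="a")
        net = TrailNetwork(1, frozenset(), frozenset({"a"}), "observed")
        ov = compute_objectives(net, m)
        assert ov.total_nodes == 1
        assert ov.avg_edge_length is None
        assert ov.avg_ti is None
        assert ov.total_length is None


class TestPercentile:
    def test_below_all_is_zero(self):
        assert percentile(0.5, [1, 2, 3]) == 0.0

    def test_median_of_1_to_100_scores_50(self):
        assert percentile(50.5, list(range(1, 101))) == 50.0

    def test_equal_to_maximum_scores_100(self):
        assert percentile(3.0, [1, 2, 3]) == 100.0

    def test_ties_counted(self):
        assert percentile(2.0, [1, 2, 2, 3]) == 75.0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            percentile(1.0, [])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        st.floats(-1e6, 1e6),
        st.floats(-1e6, 1e6),
    )
    def test_monotone_in_observed_value(self, ens, a, b):
        lo, hi = min(a, b), max(a, b)
        assert percentile(lo, ens) <= percentile(hi, ens)

    def test_adding_larger_value_strictly_decreases(self):
        ens = [1.0, 2.0, 3.0]
        assert percentile(2.0, ens + [10.0]) < percentile(2.0, ens)


class TestComparisonDifferences:
    def test_worked_pattern(self):
        df = pd.DataFrame({"pct_obs": [3.0], "pct_opt": [0.0]})
        out = comparison_differences(df)
        assert out["d_rand"].iloc[0] == pytest.approx(47.0)
        assert out["d_opt"].iloc[0] == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "obs,opt,dr,do",
        [(50.0, 50.0, 0.0, 0.0), (100.0, 0.0, -50.0, 100.0)],
    )
    def test_boundary_cases(self, obs, opt, dr, do):
        out = comparison_differences(pd.DataFrame({"pct_obs": [obs], "pct_opt": [opt]}))
        assert out["d_rand"].iloc[0] == pytest.approx(dr)
        assert out["d_opt"].iloc[0] == pytest.approx(do)


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert wilcoxon_paired(v, v) == (0.0, 1.0)

    def test_uniformly_smaller_distances_significant(self):
        rng = np.random.default_rng(5)
        d_rand = 40 + rng.normal(0, 5, 36)
        d_opt = rng.normal(3, 2, 36)
        w, p = wilcoxon_paired(d_rand, d_opt)
        assert w == 0.0  # no pair has d_opt > d_rand
        assert p < 0.05

    def test_tied_rank_hand_computation(self):
        # differences [4,4,4,4,4,-4]: all share average rank 3.5, so the
        # smaller signed-rank sum is 3.5
        d_rand = [5.0, 5.0, 5.0, 5.0, 5.0, 1.0]
        d_opt = [1.0, 1.0, 1.0, 1.0, 1.0, 5.0]
        w, _ = wilcoxon_paired(d_rand, d_opt)
        assert w == pytest.approx(3.5)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0], [2.0])


class TestFriedman:
    def test_all_equal_matrix_is_null(self):
        assert friedman(np.ones((4, 3))) == (0.0, 1.0)

    def test_perfectly_ordered_ranks_reach_closed_form(self):
        # every block ranks the treatments identically: Q = b(k-1)
        for b, k in [(4, 3), (5, 4)]:
            m = np.tile(np.arange(k, dtype=float), (b, 1))
            q, p = friedman(m)
            assert q == pytest.approx(b * (k - 1))

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            m = rng.random((4, 3)) * 10
            q, p = friedman(m)
            q2, p2 = sps.friedmanchisquare(*[m[:, j] for j in range(3)])
            assert q == pytest.approx(q2)
            assert p == pytest.approx(p2)

    def test_single_treatment_rejected(self):
        with pytest.raises(ValueError):
            friedman(np.ones((4, 1)))


class TestConoverIman:
    def test_all_equal_matrix_null(self):
        out = conover_iman(np.ones((4, 3)))
        assert (out["T"] == 0).all()
        assert (out["p_bonferroni"] == 1).all()

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        out = conover_iman(rng.random((5, 4)))
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()

    def test_matches_direct_formula_on_fixture(self):
        """Independent re-derivation: rank sums, A1, C1, T1 and the t
        denominator computed with explicit arithmetic."""
        m = np.array(
            [
                [10.0, 20.0, 30.0],
                [15.0, 25.0, 5.0],
                [20.0, 10.0, 30.0],
                [5.0, 15.0, 25.0],
            ]
        )
        out = conover_iman(m, labels=["x", "y", "z"])
        b, k = 4, 3
        ranks = np.array([[1, 2, 3], [2, 3, 1], [2, 1, 3], [1, 2, 3]], dtype=float)
        R = ranks.sum(axis=0)  # [6, 8, 10]
        A1 = float((ranks**2).sum())  # no ties: b*k(k+1)(2k+1)/6 = 56
        C1 = b * k * (k + 1) ** 2 / 4  # 48
        T1 = (k - 1) * (((R - b * (k + 1) / 2) ** 2).sum()) / (A1 - C1)
        denom = np.sqrt(2 * b * (A1 - C1) * (1 - T1 / (b * (k - 1))) / ((b - 1) * (k - 1)))
        t_xy = (R[0] - R[1]) / denom
        row = out[(out["a"] == "x") & (out["b"] == "y")].iloc[0]
        assert row["T"] == pytest.approx(t_xy)
        p = 2 * sps.t.sf(abs(t_xy), (b - 1) * (k - 1))
        assert row["p_raw"] == pytest.approx(p)
        assert row["p_bonferroni"] == pytest.approx(min(1.0, 3 * p))


class TestCorrelations:
    def _vectors(self, xs, ys):
        return [
            ObjectiveVector(avg_edge_length=1.0, total_nodes=x, avg_ti=1.5, total_length=y)
            for x, y in zip(xs, ys)
        ]

    def test_perfect_positive(self):
        xs = [1, 2, 3, 4, 5, 6]
        vecs = self._vectors(xs, [2 * x for x in xs])
        out = objective_correlations(vecs)
        row = out[(out["a"] == "total_nodes") & (out["b"] == "total_length")].iloc[0]
        assert row["spearman_r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        xs = [1, 2, 3, 4, 5, 6]
        vecs = self._vectors(xs, [-x for x in xs])
        out = objective_correlations(vecs)
        row = out[(out["a"] == "total_nodes") & (out["b"] == "total_length")].iloc[0]
        assert row["spearman_r"] == pytest.approx(-1.0)

    def test_constant_series_reported_missing(self):
        vecs = self._vectors([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        out = objective_correlations(vecs)
        row = out[(out["a"] == "total_nodes") & (out["b"] == "total_length")].iloc[0]
        assert np.isnan(row["spearman_r"])

    def test_too_few_networks_rejected(self):
        with pytest.raises(ValueError):
            objective_correlations(self._vectors([1, 2], [3, 4]))


class TestAggregation:
    def test_day_averaging(self):
        df = pd.DataFrame(
            {
                "colony": ["c1"] * 3 + ["c2"],
                "objective": ["avg_ti", "avg_ti", "total_nodes", "avg_ti"],
                "pct_obs": [40.0, 60.0, 10.0, 30.0],
            }
        )
        agg = aggregate_percentiles(df)
        assert agg.loc["c1", "avg_ti"] == pytest.approx(50.0)
        assert agg.loc["c1", "total_nodes"] == pytest.approx(10.0)
        assert agg.loc["c2", "avg_ti"] == pytest.approx(30.0)
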