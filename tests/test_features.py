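import math

import numpy as np
import pytest
from scipy import special

from seldiclass.errors import ConfigError, DataError
from seldiclass.features import (
    SearchConfig,
    rank_features,
    rate_subset,
    search_subsets,
    t_statistic,
)
from seldiclass.simulate import PeakSpec, SimConfig, generate
from seldiclass.spectra import CANCER, group_stats

from conftest import make_set


def brute_force_t(cancer_col, control_col):
    """Independent recomputation of the unpooled-variance t from raw values."""
    nd, nc = len(cancer_col), len(control_col)
    md = sum(cancer_col) / nd
    mc = sum(control_col) / nc
    vd = sum((v - md) ** 2 for v in cancer_col) / (nd - 1)
    vc = sum((v - mc) ** 2 for v in control_col) / (nc - 1)
    return (md - mc) / math.sqrt(vd / nd + vc / nc)


class TestTStatistic:
    def test_hand_arithmetic_and_df_rule(self):
        sset = make_set(
            cancer_rows=[[1, 1], [2, 2], [3, 3]],
            control_rows=[[4, 4], [5, 5], [6, 6]],
        )
        t, df, p = t_statistic(group_stats(sset), 0)
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-12)
        assert t == pytest.approx(-3.67423, abs=1e-5)
        assert df == 4
        # p cross-checked via the regularized incomplete beta form of the
        # Student-t two-sided tail, independent of scipy.stats.t
        p_beta = special.betainc(df / 2.0, 0.5, df / (df + t * t))
        assert p == pytest.approx(p_beta, rel=1e-12)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(3)
        cancer = rng.lognormal(0.0, 1.0, size=(8, 5))
        control = rng.lognormal(0.3, 0.8, size=(11, 5))
        stats = group_stats(make_set(cancer, control))
        for j in range(5):
            t, df, _ = t_statistic(stats, j)
            assert t == pytest.approx(brute_force_t(cancer[:, j], control[:, j]), rel=1e-10)
            assert df == 8 + 11 - 2

    def test_identical_groups_give_null_result(self):
        rows = [[1.0, 2.0], [3.0, 1.0], [2.0, 4.0]]
        t, _, p = t_statistic(group_stats(make_set(rows, rows)), 1)
        assert t == 0.0
        assert p == 1.0

    def test_swapping_groups_negates_t_keeps_p(self):
        cancer = [[1.0, 9.0], [2.0, 7.0], [4.0, 8.0]]
        control = [[5.0, 2.0], [6.0, 1.0], [7.0, 3.0]]
        t1, _, p1 = t_statistic(group_stats(make_set(cancer, control)), 0)
        t2, _, p2 = t_statistic(group_stats(make_set(control, cancer)), 0)
        assert t2 == pytest.approx(-t1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_zero_variance_sentinel(self):
        # feature 0: constant and equal across groups; feature 1: constant,
        # different means -> infinite-separation sentinel
        sset = make_set(
            cancer_rows=[[1.0, 5.0], [1.0, 5.0]],
            control_rows=[[1.0, 2.0], [1.0, 2.0]],
        )
        stats = group_stats(sset)
        t0, _, p0 = t_statistic(stats, 0)
        t1, _, p1 = t_statistic(stats, 1)
        assert (t0, p0) == (0.0, 1.0)
        assert t1 == np.inf and p1 == 0.0
        assert rank_features(sset).order[0] == 1  # sentinel outranks finite

    def test_p_decreases_as_abs_t_increases(self):
        from seldiclass.spectra import GroupStats

        ps = []
        for gap in (0.5, 1.0, 2.0, 4.0):
            stats = GroupStats(
                mean_cancer=np.array([gap]), mean_control=np.array([0.0]),
                var_cancer=np.array([1.0]), var_control=np.array([1.0]),
                n_cancer=10, n_control=10,
            )
            ps.append(t_statistic(stats, 0)[2])
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestRankFeatures:
    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(9)
        cancer = rng.normal(2.0, 1.0, size=(12, 8)) ** 2
        control = rng.normal(1.0, 1.0, size=(10, 8)) ** 2
        sset = make_set(cancer, control)
        ranking = rank_features(sset)
        abs_t = [abs(brute_force_t(cancer[:, j], control[:, j])) for j in range(8)]
        oracle = sorted(range(8), key=lambda j: (-abs_t[j], j))
        assert ranking.order.tolist() == oracle
        # |t| non-increasing along the rank order
        ordered = np.abs(ranking.t[ranking.order])
        assert np.all(np.diff(ordered) <= 1e-12)

    def test_engineered_magnitudes_order(self):
        # three features built so |t| ~ (small, large, middle)
        rng = np.random.default_rng(1)
        base_c = rng.normal(0.0, 1.0, size=(15, 3))
        base_n = rng.normal(0.0, 1.0, size=(15, 3))
        base_c[:, 1] += 5.0
        base_c[:, 2] += 1.5
        sset = make_set(np.abs(base_c) + 1.0, np.abs(base_n) + 1.0)
        assert rank_features(sset).order.tolist()[:2] == [1, 2]

    def test_invariant_under_common_scaling(self):
        rng = np.random.default_rng(5)
        cancer = rng.gamma(2.0, 1.0, size=(9, 6))
        control = rng.gamma(2.5, 1.0, size=(8, 6))
        r1 = rank_features(make_set(cancer, control))
        r2 = rank_features(make_set(3.0 * cancer, 3.0 * control))
        assert np.allclose(r1.t, r2.t, rtol=1e-10)
        assert r1.order.tolist() == r2.order.tolist()

    def test_planted_markers_reach_top_ranks(self):
        # delta = 2 pooled-SD units, 50/50 samples, 200 features
        noise = 0.5
        markers = tuple(
            PeakSpec(c, 2.0, 1.0, 1.0 + 2 * noise) for c in (900.0, 1100.0, 1300.0, 1500.0, 1640.0)
        )
        cfg = SimConfig(
            grid_min=700.0, grid_max=1700.0, n_points=200,
            n_control=50, n_disease=50, baseline_scale=5.0, baseline_decay=0.0,
            shared_peaks=(), marker_peaks=markers, noise_sd=noise, seed=17,
        )
        sset, truth = generate(cfg)
        top10 = set(rank_features(sset).top(10).tolist())
        assert set(truth.mz_index.tolist()) <= top10

    def test_null_type_one_error_rate_is_calibrated(self):
        # global null: both groups drawn from one distribution; the fraction
        # of features with p < 0.05 stays within 3 binomial SDs of 0.05
        rng = np.random.default_rng(23)
        cancer = rng.normal(10.0, 2.0, size=(30, 200))
        control = rng.normal(10.0, 2.0, size=(30, 200))
        ranking = rank_features(make_set(np.abs(cancer), np.abs(control)))
        prop = float(np.mean(ranking.p < 0.05))
        sd = math.sqrt(0.05 * 0.95 / 200)
        assert abs(prop - 0.05) <= 3 * sd
        assert np.all(ranking.p > 0.0) and np.all(ranking.p <= 1.0)


class TestRateSubset:
    def test_perfectly_separating_feature_rates_one(self, separable_set):
        assert rate_subset(separable_set, [0]) == 1.0

    def test_permuted_labels_destroy_separation(self, separable_set):
        rng = np.random.default_rng(2)
        matrix = separable_set.intensity_matrix()
        labels = separable_set.label_array()
        shuffled = labels[rng.permutation(len(labels))]
        scrambled = make_set(matrix[shuffled == CANCER], matrix[shuffled != CANCER])
        assert rate_subset(scrambled, [0]) <= 0.7

    def test_invariant_to_index_order(self, separable_set):
        assert rate_subset(separable_set, [2, 0, 1]) == rate_subset(separable_set, [0, 1, 2])

    def test_empty_subset_rejected(self, separable_set):
        with pytest.raises(DataError):
            rate_subset(separable_set, [])

    def test_out_of_bounds_rejected(self, separable_set):
        with pytest.raises(DataError):
            rate_subset(separable_set, [99])


class TestSearchSubsets:
    @staticmethod
    def twenty_feature_instance(seed=0):
        rng = np.random.default_rng(seed)
        cancer = rng.normal(5.0, 1.0, size=(15, 20))
        control = rng.normal(5.0, 1.0, size=(15, 20))
        cancer[:, 7] = rng.uniform(9.0, 10.0, 15)  # only feature 7 separates
        control[:, 7] = rng.uniform(1.0, 2.0, 15)
        return make_set(np.abs(cancer), np.abs(control))

    def test_singleton_search_matches_exhaustive(self):
        sset = self.twenty_feature_instance()
        best, log = search_subsets(sset, SearchConfig(k=1, seed=4))
        assert best.indices == (7,)
        assert best.rating == 1.0
        exhaustive = max(rate_subset(sset, [j]) for j in range(20))
        assert best.rating == exhaustive

    def test_planted_separators_terminate_search(self):
        rng = np.random.default_rng(6)
        cancer = np.abs(rng.normal(5.0, 1.0, size=(20, 200)))
        control = np.abs(rng.normal(5.0, 1.0, size=(20, 200)))
        for j in (10, 50, 90, 130, 170):
            cancer[:, j] += 20.0
        sset = make_set(cancer, control)
        best, log = search_subsets(sset, SearchConfig(k=5, seed=8))
        assert best.rating == 1.0
        assert len(log) <= 101  # stopped at full discrimination or budget

    def test_best_rating_log_is_non_decreasing(self):
        sset = self.twenty_feature_instance(seed=3)
        _, log = search_subsets(
            sset, SearchConfig(k=2, seed=1, max_iterations=30)
        )
        assert all(a <= b for a, b in zip(log, log[1:]))

    def test_never_worse_than_best_initial_subset(self):
        rng = np.random.default_rng(12)
        cancer = np.abs(rng.normal(5.0, 2.0, size=(10, 30)))
        control = np.abs(rng.normal(6.0, 2.0, size=(10, 30)))
        sset = make_set(cancer, control)
        best, log = search_subsets(sset, SearchConfig(k=3, seed=2, max_iterations=10))
        assert best.rating >= log[0]

    def test_k_exceeding_feature_count_rejected(self, separable_set):
        with pytest.raises(ConfigError):
            search_subsets(separable_set, SearchConfig(k=10, seed=0))
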