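import numpy as np
import pytest

from robustcheck.dataset_core import OmicsTable
from robustcheck.factor_analysis import (
    FdrResult,
    ScreenConfig,
    choose_significance_test,
    cluster_loadings,
    compute_feature_fdr,
    compute_loadings,
    filter_by_fdr,
    horns_parallel,
    logistic_variance_screen,
    pca_eigendecomposition,
    prune_tight_clusters,
    run_factor_analysis,
)


def _table(values, labels):
    values = np.asarray(values, dtype=float)
    return OmicsTable(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        feature_names=tuple(f"f{j}" for j in range(values.shape[1])),
        labels=np.asarray(labels),
    )


class TestSignificanceTriage:
    def test_type_one_error_rate_near_alpha(self):
        """Under the null the triage's p-values reject at ~5%."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_trials = 1000
        for _ in range(n_trials):
            _, p = choose_significance_test(
                rng.standard_normal(40), rng.standard_normal(40)
            )
            rejections += p <= 0.05
        assert rejections / n_trials == pytest.approx(0.05, abs=0.02)

    def test_identical_jittered_groups_give_large_p(self):
        rng = np.random.default_rng(1)
        base = np.arange(20.0)
        a = base + rng.normal(0, 1e-6, 20)
        name, p = choose_significance_test(a, base)
        assert p > 0.5

    def test_widely_separated_normals_give_tiny_p(self):
        rng = np.random.default_rng(2)
        name, p = choose_significance_test(
            rng.normal(0, 1, 20), rng.normal(5, 1, 20)
        )
        assert p < 1e-6
        assert name in ("student_t", "welch_t")

    def test_zero_variance_group_routed_to_rank_test(self):
        name, p = choose_significance_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert name == "mann_whitney_u"
        assert 0 <= p <= 1

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            choose_significance_test([1.0], [1.0, 2.0])


class TestLeaveOutFdr:
    def test_perfect_separation_brute_force_all_36_pvalues(self):
        """Classes {1..4} vs {101..104}: every leave-out test is significant."""
        table = _table(
            np.array([1, 2, 3, 4, 101, 102, 103, 104], float)[:, None],
            [0, 0, 0, 0, 1, 1, 1, 1],
        )
        result = compute_feature_fdr(table, max_leave_out=2)
        assert result.n_total[0] == 8 + 28  # N + C(N,2) leave-out sets
        assert result.n_above[0] == 0
        assert result.fdr[0] == 0.0

    def test_null_feature_fdr_near_one(self):
        rng = np.random.default_rng(5)
        table = _table(rng.standard_normal((60, 1)), np.tile([0, 1], 30))
        result = compute_feature_fdr(table, max_leave_out=1)
        # identical class distributions: ~95% of p-values exceed 0.05
        assert result.fdr[0] > 0.7

    def test_fdr_is_exact_integer_ratio(self):
        rng = np.random.default_rng(6)
        values = np.column_stack(
            [rng.standard_normal(12), rng.standard_normal(12) + np.tile([0, 3], 6)]
        )
        table = _table(values, np.tile([0, 1], 6))
        result = compute_feature_fdr(table, max_leave_out=2)
        recovered = result.fdr * result.n_total
        assert np.allclose(recovered, np.round(recovered), atol=1e-9)

    def test_depth_one_ratio(self):
        fdr = FdrResult(
            feature_names=("f",), fdr=np.array([2 / 6]),
            n_above=np.array([2]), n_total=np.array([6]), leave_out_depth=1,
        )
        assert fdr.fdr[0] == pytest.approx(1 / 3)

    def test_max_pairs_subsamples_pair_count(self):
        rng = np.random.default_rng(7)
        table = _table(rng.standard_normal((20, 1)), np.tile([0, 1], 10))
        result = compute_feature_fdr(table, max_leave_out=2, max_pairs=30, seed=0)
        assert result.n_total[0] == 20 + 30


class TestFdrFilter:
    def test_boundary_exactly_at_threshold_kept(self):
        fdr = FdrResult(
            feature_names=("a", "b", "c"),
            fdr=np.array([0.0, 0.1, 0.11]),
            n_above=np.array([0, 10, 11]),
            n_total=np.array([100, 100, 100]),
        )
        assert filter_by_fdr(fdr, threshold=0.1) == ["a", "b"]

    def test_all_zero_all_kept(self):
        fdr = FdrResult(
            feature_names=("a", "b"), fdr=np.zeros(2),
            n_above=np.zeros(2, int), n_total=np.full(2, 10),
        )
        assert filter_by_fdr(fdr) == ["a", "b"]

    def test_all_one_raises_no_significant_features(self):
        fdr = FdrResult(
            feature_names=("a",), fdr=np.ones(1),
            n_above=np.full(1, 10), n_total=np.full(1, 10),
        )
        with pytest.raises(ValueError, match="no significant features"):
            filter_by_fdr(fdr)


def _planted_factor_data(seed, n=200, m=10, strength=0.9, noise_sd=0.3):
    """Two orthogonal planted factors, each loading on half the features."""
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 2))
    load = np.zeros((m, 2))
    load[: m // 2, 0] = strength
    load[m // 2 :, 1] = strength
    x = g @ load.T + noise_sd * rng.standard_normal((n, m))
    return (x - x.mean(0)) / x.std(0, ddof=1)


class TestHornsParallel:
    def test_recovers_two_planted_factors(self):
        x = _planted_factor_data(seed=0)
        assert horns_parallel(x, n_iter=200, seed=0) == 2

    def test_planted_factor_count_recovered_across_seeds(self):
        hits = sum(
            horns_parallel(_planted_factor_data(seed=s), n_iter=150, seed=s) == 2
            for s in range(20)
        )
        assert hits >= 18  # >= 90% of seeds

    def test_pure_noise_raises_no_structure(self):
        failures = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            x = rng.standard_normal((500, 10))
            try:
                horns_parallel(x, n_iter=150, seed=s)
            except ValueError:
                failures += 1
        assert failures >= 19  # k = 0 on >= 95% of null seeds

    def test_deterministic_for_fixed_seed(self):
        x = _planted_factor_data(seed=3)
        assert horns_parallel(x, n_iter=150, seed=9) == horns_parallel(
            x, n_iter=150, seed=9
        )

    def test_n_iter_floor_enforced(self):
        with pytest.raises(ValueError):
            horns_parallel(_planted_factor_data(seed=1), n_iter=50)


class TestLoadings:
    def test_as_printed_convention_divides_by_root_eigenvalue(self):
        lm = compute_loadings(np.array([4.0, 1.0]), np.eye(2), k=2)
        assert np.allclose(lm.A, np.diag([0.5, 1.0]))

    def test_conventional_alternative_multiplies(self):
        lm = compute_loadings(np.array([4.0, 1.0]), np.eye(2), k=2, exponent_convention=0.5)
        assert np.allclose(lm.A, np.diag([2.0, 1.0]))

    def test_sign_pattern_identical_between_conventions(self):
        x = _planted_factor_data(seed=4)
        eigvals, eigvecs = pca_eigendecomposition(x)
        down = compute_loadings(eigvals, eigvecs, k=2, exponent_convention=-0.5)
        up = compute_loadings(eigvals, eigvecs, k=2, exponent_convention=0.5)
        assert np.array_equal(np.sign(down.A), np.sign(up.A))

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_loadings(np.array([1.0, 0.0]), np.eye(2), k=2)


class TestClusterLoadings:
    def test_coincident_far_apart_clusters_score_one(self):
        points = np.array([[0.0], [0.0], [0.0], [9.0], [9.0], [9.0]])
        sol = cluster_loadings(points, k_range=[2], seed=0)
        assert np.allclose(sol.silhouettes, 1.0)

    def test_hand_computed_silhouette_08(self):
        """1-D clusters {0,1} and {5,6}: a=1, b=5, s=(5-1)/5=0.8."""
        points = np.array([[0.0], [1.0], [5.0], [6.0]])
        sol = cluster_loadings(points, k_range=[2], seed=0)
        assert np.allclose(sorted(sol.within), [1.0, 1.0])
        assert np.allclose(sorted(sol.neighbor), [5.0, 5.0])
        assert np.allclose(sol.silhouettes, 0.8)

    def test_silhouette_values_bounded(self):
        rng = np.random.default_rng(8)
        points = rng.standard_normal((15, 3))
        sol = cluster_loadings(points, seed=0)
        assert np.all(sol.silhouettes >= -1) and np.all(sol.silhouettes <= 1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cluster_loadings(np.zeros((2, 2)), seed=0)


class TestPruneTightClusters:
    def test_tight_cluster_capped_at_three(self):
        # cluster 0: five near-coincident points; cluster 1: four spread points
        points = np.vstack(
            [np.array([[0.0], [0.01], [0.02], [0.03], [0.04]]),
             np.array([[5.0], [6.5], [8.0], [9.5]])]
        )
        sol = cluster_loadings(points, k_range=[2], seed=0)
        names = [f"f{i}" for i in range(9)]
        tight = int(sol.labels[0])
        assert sol.silhouettes[tight] >= 0.5
        kept = prune_tight_clusters(sol, points, names)
        loose_size = int((sol.labels != tight).sum())
        if sol.silhouettes[1 - tight] >= 0.5:
            loose_size = min(loose_size, 3)
        assert len(kept) == 3 + loose_size

    def test_all_loose_clusters_pass_through(self):
        points = np.arange(6.0)[:, None]
        sol = cluster_loadings(points, k_range=[2], seed=0)
        names = [f"f{i}" for i in range(6)]
        kept = prune_tight_clusters(sol, points, names, silhouette_threshold=1.1)
        assert kept == names

    def test_tight_cluster_of_exactly_three_kept_whole(self):
        points = np.array([[0.0], [0.0], [0.0], [9.0], [9.0], [9.0]])
        sol = cluster_loadings(points, k_range=[2], seed=0)
        kept = prune_tight_clusters(sol, points, [f"f{i}" for i in range(6)])
        assert len(kept) == 6


class TestLogisticVarianceScreen:
    def test_scaled_variances_match_analytic_w_squared(self):
        rng = np.random.default_rng(9)
        w_true = np.array([2.0, 1.0, 0.9])
        x = rng.standard_normal((4000, 3))
        logits = x @ w_true
        y = (logits + rng.logistic(size=4000) > 0).astype(int)
        w, scaled, kept = logistic_variance_screen(
            x, y, ["a", "b", "c"], n_draws=100_000, seed=0
        )
        analytic = 8 * w**2 / (w**2).max()
        assert np.allclose(scaled, analytic, rtol=0.05)
        assert scaled.max() == 8.0

    def test_retention_rule_matches_half_max_weight_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((3000, 4))
        w_true = np.array([2.0, 1.2, 0.5, 0.1])
        y = (x @ w_true + rng.logistic(size=3000) > 0).astype(int)
        w, scaled, kept = logistic_variance_screen(
            x, y, ["a", "b", "c", "d"], n_draws=50_000, seed=1
        )
        oracle = [n for n, wf in zip("abcd", w) if abs(wf) >= 0.5 * np.abs(w).max()]
        assert kept == oracle

    def test_single_feature_always_retained_at_eight(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((200, 1))
        y = (x[:, 0] + rng.logistic(size=200) > 0).astype(int)
        w, scaled, kept = logistic_variance_screen(x, y, ["solo"], n_draws=5000, seed=2)
        assert scaled[0] == 8.0
        assert kept == ["solo"]


class TestFullScreen:
    def test_planted_feature_recovery_on_reference_fixture(
        self, reference_table, reference_screen
    ):
        _, truth = reference_table
        result = reference_screen
        assert set(result.F_star) <= set(result.F_doubleprime) <= set(result.F_prime)
        assert len(set(result.F_star) & set(truth)) >= 4
        assert len(set(result.F_star) - set(truth)) <= 2
        assert result.scaled_variances.max() == 8.0

    def test_uninformative_table_raises_in_fdr_stage(self):
        rng = np.random.default_rng(12)
        table = _table(rng.standard_normal((30, 4)), np.tile([0, 1], 15))
        with pytest.raises(ValueError, match="FDR stage.*no significant features"):
            run_factor_analysis(table, ScreenConfig(max_leave_out=1, seed=0))

    def test_deterministic_for_fixed_seed(self, small_planted_table):
        table, _ = small_planted_table
        config = ScreenConfig(max_leave_out=1, n_draws=5000, horn_iter=150, seed=3)
        r1 = run_factor_analysis(table, config)
        r2 = run_factor_analysis(table, config)
        assert r1.F_star == r2.F_star
        assert np.array_equal(r1.scaled_variances, r2.scaled_variances)
        assert np.array_equal(r1.fdr.fdr, r2.fdr.fdr)
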