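import numpy as np
import pytest

from nemtie.data import split_cohort, standardize
from nemtie.network import CVProtocol, build_entropy_matrix, normalize_adjacency
from nemtie.selection import (
    LossConfig,
    PSOConfig,
    composite_auc_loss,
    evaluate_threshold,
    fit_final_model,
    greedy_feature_subset,
    pso_optimize_threshold,
    select_features,
)

from conftest import make_table


class TestCompositeAucLoss:
    @pytest.mark.parametrize(
        "alpha,beta,tr,te,expected",
        [
            (0.5, 0.5, 1.0, 0.5, 0.75),
            (1.0, 0.0, 0.9, 0.1, 0.9),
            (0.5, 0.5, 0.73, 0.73, 0.73),
        ],
    )
    def test_convex_combination(self, alpha, beta, tr, te, expected):
        config = LossConfig(alpha=alpha, beta=beta)
        assert composite_auc_loss(tr, te, config) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_auc_rejected(self):
        with pytest.raises(ValueError):
            composite_auc_loss(1.2, 0.5, LossConfig())

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=0.7, beta=0.5)
        with pytest.raises(ValueError):
            LossConfig(alpha=-0.2, beta=1.2)


class TestPsoOptimizeThreshold:
    def test_recovers_quadratic_optimum(self):
        config = PSOConfig(n_particles=20, n_iterations=100, seed=0)
        t_star, _, _ = pso_optimize_threshold(lambda t: -((t - 0.3) ** 2), config)
        assert abs(t_star - 0.3) < 1e-3

    def test_constant_objective_stays_in_bounds(self):
        config = PSOConfig(seed=1, n_iterations=20)
        t_star, val, trace = pso_optimize_threshold(lambda t: 0.5, config)
        assert 0.0 <= t_star <= 1.0
        assert np.all(trace == 0.5)

    def test_best_value_trace_monotone_non_decreasing(self):
        rng = np.random.default_rng(2)

        def noisy(t):
            return float(np.sin(7 * t) + 0.01 * rng.standard_normal())

        _, _, trace = pso_optimize_threshold(noisy, PSOConfig(seed=2, n_iterations=50))
        assert np.all(np.diff(trace) >= 0)

    def test_deterministic_for_fixed_seed(self):
        f = lambda t: -((t - 0.62) ** 2)
        a = pso_optimize_threshold(f, PSOConfig(seed=9))
        b = pso_optimize_threshold(f, PSOConfig(seed=9))
        assert a[0] == b[0] and np.array_equal(a[2], b[2])

    def test_non_finite_objective_rejected(self):
        with pytest.raises(ValueError):
            pso_optimize_threshold(lambda t: float("nan"), PSOConfig(seed=0, n_iterations=2))

    def test_needs_two_particles(self):
        with pytest.raises(ValueError):
            PSOConfig(n_particles=1)


@pytest.fixture(scope="module")
def planted_setup():
    """Small table: 3-feature planted block among noise, split and network."""
    rng = np.random.default_rng(10)
    m = 100
    y = np.array(([0] * 7 + [1] * 3) * 10)
    X = rng.standard_normal((m, 30))
    shared = rng.standard_normal(m)
    for j in range(3):
        X[:, j] = np.sqrt(0.5) * shared + np.sqrt(0.5) * X[:, j] + 2.0 * y
    table = make_table(X, y)
    split = split_cohort(table, seed=10)
    table_std, _ = standardize(table, split.train_idx)
    net = normalize_adjacency(
        build_entropy_matrix(table_std, cv=CVProtocol(seed=10, n_repeats=2))
    )
    return table_std, split, net


class TestEvaluateThreshold:
    def test_T_one_scores_at_chance(self, planted_setup):
        table, split, net = planted_setup
        loss, modules, union = evaluate_threshold(1.0, table, split, net)
        assert loss == 0.5 and len(modules) == 0 and union == []

    def test_loss_in_unit_interval(self, planted_setup):
        table, split, net = planted_setup
        for T in [0.0, 0.3, 0.6, 0.9]:
            loss, _, _ = evaluate_threshold(T, table, split, net)
            assert 0.0 <= loss <= 1.0

    def test_some_threshold_beats_chance_strongly(self, planted_setup):
        table, split, net = planted_setup
        best = max(
            evaluate_threshold(T, table, split, net)[0] for T in np.linspace(0, 0.9, 10)
        )
        assert best > 0.9


class TestGreedyFeatureSubset:
    def test_perfect_feature_selected_first(self, toy_table):
        split = split_cohort(toy_table, ratios=(0.6, 0.2, 0.2), seed=0)
        selected, trace = greedy_feature_subset([0, 1], toy_table, split)
        assert selected[0] == 0

    def test_exact_duplicate_never_added(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 30)
        f = y + 0.3 * rng.standard_normal(60)
        table = make_table(np.column_stack([f, f, rng.standard_normal(60)]), y)
        split = split_cohort(table, seed=1)
        selected, _ = greedy_feature_subset([0, 1, 2], table, split)
        assert not ({0, 1} <= set(selected))

    def test_trace_strictly_increasing(self, planted_setup):
        table, split, net = planted_setup
        _, _, union = evaluate_threshold(0.5, table, split, net)
        if not union:
            pytest.skip("degenerate threshold for this fixture")
        _, trace = greedy_feature_subset(union, table, split)
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_exhaustive_at_least_as_good_as_greedy(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 25)
        X = rng.standard_normal((50, 6))
        X[:, 0] += 1.2 * y
        X[:, 4] += 0.8 * y
        table = make_table(X, y)
        split = split_cohort(table, seed=2)
        cands = list(range(6))
        greedy_sel, greedy_trace = greedy_feature_subset(cands, table, split)
        exh_sel, exh_trace = greedy_feature_subset(cands, table, split, exhaustive=True)
        assert exh_trace[-1] >= greedy_trace[-1] - 1e-12

    def test_empty_candidates_rejected(self, toy_table):
        split = split_cohort(toy_table, ratios=(0.6, 0.2, 0.2), seed=0)
        with pytest.raises(ValueError):
            greedy_feature_subset([], toy_table, split)


class TestFitFinalModel:
    def test_separable_toy_train_auc_one(self, toy_table):
        from nemtie.baselines import auc_score

        split = split_cohort(toy_table, ratios=(0.6, 0.2, 0.2), seed=0)
        scores = fit_final_model(toy_table, split, [0])
        assert auc_score(scores["train"], toy_table.C[split.train_idx]) == 1.0

    def test_deterministic_scores(self, planted_setup):
        table, split, _ = planted_setup
        a = fit_final_model(table, split, [0, 1])
        b = fit_final_model(table, split, [0, 1])
        for name in ("train", "test", "validation"):
            np.testing.assert_array_equal(a[name], b[name])

    def test_label_permutation_breaks_signal(self):
        rng = np.random.default_rng(6)
        from nemtie.baselines import auc_score

        aucs = []
        for rep in range(5):
            y = np.array([0, 1] * 50)
            X = rng.standard_normal((100, 4))
            X[:, 0] += 2.0 * y
            yp = rng.permutation(y)
            table = make_table(X, yp)
            split = split_cohort(table, seed=rep)
            scores = fit_final_model(table, split, [0, 1])
            aucs.append(auc_score(scores["test"], table.C[split.test_idx]))
        assert abs(np.mean(aucs) - 0.5) <= 0.15


class TestSelectFeatures:
    def test_end_to_end_determinism_and_constraint(self, planted_setup):
        table, split, net = planted_setup
        kwargs = dict(
            loss_config=LossConfig(),
            pso_config=PSOConfig(seed=5, n_particles=10, n_iterations=20),
            n_boot=50,
        )
        a = select_features(table, split, net, **kwargs)
        b = select_features(table, split, net, **kwargs)
        assert a.T_star == b.T_star
        assert a.selected_features == b.selected_features
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)
        # every selected feature traces back to a clique-percolation module
        union = set(a.modules_used.feature_union())
        assert set(a.selected_indices) <= union
        assert np.all(np.diff(a.loss_trace) >= 0)

    def test_holdout_tuning_keeps_test_split_out(self, planted_setup):
        table, split, net = planted_setup
        res = select_features(
            table, split, net,
            pso_config=PSOConfig(seed=6, n_particles=8, n_iterations=10),
            holdout_tuning=True, n_boot=20,
        )
        assert set(res.selected_indices) <= set(res.modules_used.feature_union())
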