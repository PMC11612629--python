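import numpy as np
import pandas as pd
import pytest

from pmpso import PMPSOSelector, SwarmConfig, constriction_factor, pearson_r, pmpso
from pmpso.selection import (
    FitnessEvaluator,
    FitnessSpec,
    PbestRecord,
    better_than,
    binarize_position,
    evaluate_fitness,
    feature_importance,
    redundancy_filter,
    run_mpso,
    top_k,
    update_velocity,
)


class TestConstrictionFactor:
    def test_standard_value(self):
        # closed form at c = 4.1: 2 / (2.1 + sqrt(0.41))
        assert constriction_factor(2.05, 2.05) == pytest.approx(0.7298, abs=2e-4)

    def test_inactive_below_four(self):
        with pytest.warns(UserWarning):
            assert constriction_factor(1.0, 1.0) == 1.0

    def test_decreasing_in_c(self):
        phi5 = constriction_factor(3.0, 2.0)
        phi6 = constriction_factor(3.0, 3.0)
        assert 0 < phi6 < phi5 < 1


class TestVelocityUpdate:
    def test_fixed_point(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0, 0.0, 1.0])
        v = np.array([0.5, -0.5, 0.25])
        out = update_velocity(v, x, x.astype(int), x.astype(int),
                              w=0.7, phi=0.73, c1=2.05, c2=2.05, v_max=4.0, rng=rng)
        np.testing.assert_allclose(out, 0.7 * v)

    def test_phi_zero_degenerate(self):
        rng = np.random.default_rng(0)
        out = update_velocity(np.ones(4), np.zeros(4), np.ones(4, int), np.ones(4, int),
                              w=0.5, phi=0.0, c1=2.05, c2=2.05, v_max=4.0, rng=rng)
        np.testing.assert_allclose(out, 0.5)

    def test_hand_value_and_clamp(self):
        class FixedRng:
            def random(self, d):
                return np.full(d, 0.5)

        out = update_velocity(np.zeros(1), np.zeros(1), np.ones(1, int), np.ones(1, int),
                              w=0.5, phi=0.7298, c1=2.05, c2=2.05, v_max=4.0,
                              rng=FixedRng())
        assert out[0] == pytest.approx(0.7298 * (2.05 * 0.5 + 2.05 * 0.5), abs=1e-6)
        clamped = update_velocity(np.zeros(1), np.zeros(1), np.ones(1, int),
                                  np.ones(1, int), w=0.5, phi=0.7298, c1=2.05,
                                  c2=2.05, v_max=1.0, rng=FixedRng())
        assert clamped[0] == 1.0

    def test_always_within_vmax(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = update_velocity(rng.normal(size=8, scale=10), rng.normal(size=8),
                                rng.integers(0, 2, 8), rng.integers(0, 2, 8),
                                w=0.9, phi=0.73, c1=2.05, c2=2.05, v_max=4.0, rng=rng)
            assert np.all(np.abs(v) <= 4.0)


class TestBinarize:
    def test_saturation(self):
        rng = np.random.default_rng(0)
        assert binarize_position(np.full(20, 20.0), rng).sum() == 20
        low = binarize_position(np.array([-20.0, -20.0, 5.0]), rng)
        assert low[0] == 0 and low[1] == 0

    def test_degenerate_mask_forced(self):
        rng = np.random.default_rng(0)
        pos = np.array([-20.0, -20.0, -19.0, -20.0])
        mask = binarize_position(pos, rng)
        assert mask.sum() == 1 and mask[2] == 1


class TestFitness:
    def test_perfect_feature(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60)
        X = np.column_stack([y.astype(float), rng.normal(size=60)])
        acc, size = evaluate_fitness(np.array([1, 0]), X, y)
        assert acc == 1.0 and size == 1

    def test_noise_features_at_chance(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1, 2], 60)
        X = rng.normal(size=(180, 3))
        acc, _ = evaluate_fitness(np.array([1, 1, 1]), X, y)
        assert abs(acc - 1 / 3) < 0.15  # binomial tolerance around chance

    def test_empty_mask_contract(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        y = np.array([0, 1] * 15)
        assert evaluate_fitness(np.zeros(2, int), X, y) == (0.0, 0)

    def test_cache_consistency(self, toy_table):
        X, y, _ = toy_table
        fit = FitnessEvaluator(X.to_numpy(), y, FitnessSpec())
        m = np.array([1, 0, 1, 0, 0, 0, 0, 0])
        assert fit(m) == fit(m)


class TestBetterThan:
    @pytest.mark.parametrize("cand, inc, expected", [
        ((0.95, 10), (0.93, 3), True),   # accuracy dominates
        ((0.95, 4), (0.95, 7), True),    # tie broken by smaller subset
        ((0.95, 7), (0.95, 7), False),   # no strict improvement
        ((0.90, 1), (0.95, 7), False),
    ])
    def test_rules(self, cand, inc, expected):
        assert better_than(cand, inc) is expected


class TestRunMpso:
    def test_bitwise_reproducible(self, toy_table):
        X, y, _ = toy_table
        cfg = SwarmConfig(n_particles=4, max_iters=3, seed=123)
        h1, g1 = run_mpso(X, y, cfg)
        h2, g2 = run_mpso(X, y, cfg)
        assert g1["fitness"] == g2["fitness"]
        np.testing.assert_array_equal(g1["mask"], g2["mask"])
        for s1, s2 in zip(h1, h2):
            for r1, r2 in zip(s1, s2):
                np.testing.assert_array_equal(r1.mask, r2.mask)

    def test_gbest_monotone_over_iterations(self, toy_table):
        X, y, _ = toy_table
        cfg = SwarmConfig(n_particles=6, max_iters=8, seed=5)
        history, _ = run_mpso(X, y, cfg)
        best_per_iter = [max(r.fitness for r in snap) for snap in history]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best_per_iter, best_per_iter[1:]))

    def test_identical_columns_collapse_to_one(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 40)
        col = y + rng.normal(0, 0.1, 80)
        X = pd.DataFrame({f"f{j}": col for j in range(4)})
        cfg = SwarmConfig(n_particles=10, max_iters=10, seed=2)
        _, gbest = run_mpso(X, y, cfg)
        assert gbest["size"] == 1  # tie-break forces the minimum subset


class TestImportanceAndTopK:
    def _history(self):
        return [[
            PbestRecord(np.array([1, 1, 0]), 0.8, 2),
            PbestRecord(np.array([1, 0, 0]), 0.4, 1),
        ]]

    def test_weights(self):
        imp = feature_importance(self._history(), ["a", "b", "c"])
        assert imp["a"] == pytest.approx(1.0)  # present in every pbest
        assert imp["b"] == pytest.approx(0.8 / 1.2)
        assert imp["c"] == 0.0  # never selected

    def test_symmetry(self):
        hist = [[PbestRecord(np.array([1, 1, 0]), 0.9, 2)]]
        imp = feature_importance(hist, ["a", "b", "c"])
        assert imp["a"] == imp["b"]

    def test_top_k_order_and_ties(self):
        imp = {"a": 0.9, "b": 0.5, "c": 0.1}
        assert top_k(imp, 2) == ["a", "b"]
        assert top_k(imp, 3) == ["a", "b", "c"]
        tied = {"a": 0.5, "b": 0.9, "c": 0.5}
        assert top_k(tied, 2) == ["b", "a"]  # canonical order breaks the tie

    def test_top_k_validation(self):
        with pytest.raises(ValueError):
            top_k({"a": 1.0}, 0)
        with pytest.raises(ValueError):
            top_k({"a": 1.0}, 2)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [6, 4, 5]) == pytest.approx(-0.5)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestRedundancyFilter:
    def test_greedy_rule(self):
        rng = np.random.default_rng(0)
        n = 500
        f1 = rng.normal(size=n)
        f2 = f1 + rng.normal(0, 0.3, n)   # |r| > 0.6 with f1
        f3 = rng.normal(size=n)           # independent
        df = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
        kept, r_table = redundancy_filter(df, ["f1", "f2", "f3"], 0.6)
        assert kept == ["f1", "f3"]
        assert all(abs(r) <= 1 for _, _, r in r_table)

    def test_nothing_removed_when_uncorrelated(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("abcd"))
        kept, _ = redundancy_filter(df, list("abcd"), 0.6)
        assert kept == list("abcd")

    def test_single_feature_kept(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        kept, r_table = redundancy_filter(df, ["a"], 0.5)
        assert kept == ["a"] and r_table == []

    def test_zero_variance_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        with pytest.warns(UserWarning, match="zero-variance"):
            kept, _ = redundancy_filter(df, ["a", "b"], 0.6)
        assert kept == ["a"]


class TestPmpsoComposition:
    def test_top_k_enters_filter(self, eeg_features):
        X, y = eeg_features
        cfg = SwarmConfig(n_particles=6, max_iters=4, seed=0, top_k=10)
        res = pmpso(X, y, cfg)
        assert len(res.ranked_top_k) == 10
        assert set(res.final_subset) <= set(res.ranked_top_k)
        # pairwise |r| bound holds on the output by construction
        for a in res.final_subset:
            for b in res.final_subset:
                if a < b:
                    assert abs(pearson_r(X[a], X[b])) <= cfg.delta + 1e-12

    def test_deterministic_result(self, toy_table):
        X, y, _ = toy_table
        cfg = SwarmConfig(n_particles=5, max_iters=4, seed=9, top_k=4)
        r1 = pmpso(X, y, cfg)
        r2 = pmpso(X, y, cfg)
        assert r1.to_dict() == r2.to_dict()


class TestSelectorEstimator:
    def test_fit_transform_support(self, toy_table):
        X, y, _ = toy_table
        sel = PMPSOSelector(n_particles=6, max_iters=5, top_k=4, random_state=1)
        Xt = sel.fit_transform(X, y)
        assert Xt.shape[0] == X.shape[0]
        assert Xt.shape[1] == sel.get_support().sum() == len(
            sel.selection_result_.final_subset)

    def test_in_sklearn_pipeline(self, toy_table):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.pipeline import Pipeline

        X, y, _ = toy_table
        pipe = Pipeline([
            ("select", PMPSOSelector(n_particles=5, max_iters=3, top_k=4,
                                     random_state=0)),
            ("clf", RandomForestClassifier(n_estimators=10, random_state=0)),
        ])
        pipe.fit(X, y)
        assert pipe.score(X, y) > 0.5

    def test_get_set_params(self):
        sel = PMPSOSelector(delta=0.4)
        assert sel.get_params()["delta"] == 0.4
        sel.set_params(top_k=5)
        assert sel.top_k == 5


def test_positions_bounded_under_constriction():
    """With the constriction factor active, particle positions do not diverge
    over a long run on a frozen fitness."""
    rng = np.random.default_rng(0)
    d, n = 6, 8
    phi = constriction_factor(2.05, 2.05)
    pos = rng.uniform(-1, 1, (n, d))
    vel = np.zeros((n, d))
    pbest = rng.integers(0, 2, (n, d))
    gbest = rng.integers(0, 2, d)
    for t in range(500):
        w = 0.9 + (0.4 - 0.9) * t / 499
        for i in range(n):
            vel[i] = update_velocity(vel[i], pos[i], pbest[i], gbest,
                                     w, phi, 2.05, 2.05, 4.0, rng)
        pos += vel
    assert np.all(np.abs(pos) < 100)
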