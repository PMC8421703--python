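"""LOOCV prediction engine, permutation inference, important nodes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import varicpm as v
from conftest import naive_loocv


def _fm(x, scope="global", kind="contrast"):
    return v.FeatureMatrix(kind=kind, values=x, normalization_scope=scope)


class TestSelectFeatures:
    def test_perfect_correlation_selected_at_any_alpha(self, rng):
        x = rng.standard_normal((10, 5))
        y = x[:, 3].copy()
        pos, neg = v.select_features(x, y, alpha=1e-6)
        assert 3 in pos and len(neg) == 0

    def test_matches_pearsonr_oracle(self, rng):
        x = rng.standard_normal((10, 5))
        y = rng.standard_normal(10)
        pos, neg = v.select_features(x, y, alpha=0.3)
        for k in range(5):
            r, p = stats.pearsonr(x[:, k], y)
            assert (k in pos) == (p < 0.3 and r > 0)
            assert (k in neg) == (p < 0.3 and r < 0)

    def test_null_selection_fraction_near_alpha(self):
        """Independent features: ~5% of nodes selected on average at alpha=.05."""
        rng = np.random.default_rng(99)
        frac = []
        for _ in range(200):
            x = rng.standard_normal((60, 50))
            y = rng.standard_normal(60)
            pos, neg = v.select_features(x, y, 0.05)
            frac.append((len(pos) + len(neg)) / 50)
        assert np.mean(frac) == pytest.approx(0.05, abs=0.01)

    def test_degenerate_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            v.select_features(rng.standard_normal((8, 3)), np.ones(8), 0.05)


class TestFeatureStrengths:
    def test_quoted_rule_arithmetic(self):
        row = np.array([0.0, 2.0, -3.0])
        s_pos, s_neg, s_tot = v.feature_strengths(row, [1], [2])
        assert (s_pos, s_neg, s_tot) == (2.0, 3.0, 2.5)

    def test_single_defined_strength_is_total(self):
        row = np.array([4.0, 6.0])
        s_pos, s_neg, s_tot = v.feature_strengths(row, [0, 1], [])
        assert s_neg is None and s_tot == s_pos == 5.0

    def test_zero_features_give_zero_strengths(self):
        s = v.feature_strengths(np.zeros(4), [0], [1])
        assert s == (0.0, -0.0, 0.0)

    def test_both_empty_is_no_feature_signal(self):
        assert v.feature_strengths(np.ones(3), [], []) == (None, None, None)

    def test_pooled_strategy_weights_by_count(self):
        row = np.array([2.0, 4.0, -3.0])
        _, _, s_tot = v.feature_strengths(row, [0, 1], [2], total_strategy="pooled")
        assert s_tot == pytest.approx((2 + 4 + 3) / 3)


class TestLoocv:
    def test_sixty_iterations_each_excluding_one(self, rng):
        x = rng.standard_normal((60, 6))
        y = x[:, 0] + 0.1 * rng.standard_normal(60)
        res = v.loocv_predict(_fm(x), y)
        assert res.n_iterations == 60
        assert len(res.iteration_sets) == 60
        # every participant got exactly one held-out prediction
        assert np.all(np.isfinite(res.predicted["total"]))

    def test_noiseless_planted_effect_predicts_near_perfectly(self):
        spec = v.CohortSpec(
            n_participants=30, n_nodes=12, task_scans=0,
            effect_nodes=tuple(range(1, 13)), effect_size_interaction=2.0,
            noise_sd=0.0, effect_node_correlation=0.97, seed=21,
        )
        t = v.draw_variability_targets(spec)
        beh, gt = v.generate_behavior(spec, t.rest)
        fm = v.interaction_features(t.rest, gt.interdependence)
        res = v.loocv_predict(fm, beh["recovery"].to_numpy())
        assert res.r["total"] > 0.99

    def test_matches_naive_reimplementation(self, rng):
        x = rng.standard_normal((8, 5))
        y = 0.8 * x[:, 0] - 0.5 * x[:, 4] + 0.3 * rng.standard_normal(8)
        res = v.loocv_predict(_fm(x), y, v.ModelConfig(selection_alpha=0.2))
        oracle = naive_loocv(x, y, alpha=0.2)
        for m in ("total", "positive", "negative"):
            pr, orc = res.predicted[m], oracle[m][0]
            if np.all(np.isfinite(orc)):
                np.testing.assert_allclose(pr, orc, atol=1e-10)

    def test_row_order_invariance(self, rng):
        x = rng.standard_normal((12, 6))
        y = x[:, 1] + rng.standard_normal(12)
        perm = rng.permutation(12)
        r1 = v.loocv_predict(_fm(x), y)
        r2 = v.loocv_predict(_fm(x[perm]), y[perm])
        np.testing.assert_allclose(r1.predicted["total"][perm], r2.predicted["total"], atol=1e-10)

    def test_invalid_model_flagged_with_reason(self, rng):
        x = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        res = v.loocv_predict(_fm(x), y, v.ModelConfig(selection_alpha=1e-9))
        assert not res.valid["total"]
        assert "no feature" in res.invalid_reason["total"]
        assert res.r["total"] is None


class TestPermutation:
    def test_bookkeeping_conservation(self, rng):
        x = rng.standard_normal((20, 60))
        y = x[:, 0] * 2 + 0.5 * rng.standard_normal(20)
        cfg = v.ModelConfig(n_permutations=50, permutation_seed=5)
        perm = v.permutation_test(_fm(x), y, cfg)
        for m, null in perm.null_r.items():
            assert perm.n_invalid_permutations[m] + null.size == 50

    def test_strong_planted_effect_is_significant(self, rng):
        # a coherent 10-node signal cluster dominating the selected sets
        z = rng.standard_normal(40)
        x = rng.standard_normal((40, 100))
        x[:, :10] = z[:, None] + 0.3 * rng.standard_normal((40, 10))
        y = z + 0.1 * rng.standard_normal(40)
        cfg = v.ModelConfig(n_permutations=200, permutation_seed=3)
        perm = v.permutation_test(_fm(x), y, cfg)
        assert perm.empirical_p["total"] <= 0.01
        assert perm.empirical_p["positive"] <= 0.01

    def test_reproducible_under_seed(self, rng):
        x = rng.standard_normal((15, 60))
        y = x[:, 0] + rng.standard_normal(15)
        cfg = v.ModelConfig(n_permutations=30, permutation_seed=11)
        p1 = v.permutation_test(_fm(x), y, cfg)
        p2 = v.permutation_test(_fm(x), y, cfg)
        for m in p1.null_r:
            np.testing.assert_array_equal(p1.null_r[m], p2.null_r[m])

    def test_batched_null_equals_per_permutation_loop(self, rng):
        """The vectorized null engine is exactly the per-permutation rerun."""
        from varicpm.prediction import _build_folds, _critical_r, _null_r, _null_r_batch

        x = rng.standard_normal((18, 30))
        y = x[:, 0] + rng.standard_normal(18)
        fm = _fm(x)
        folds = _build_folds(fm)
        rc = _critical_r(0.05, 15)
        ys = np.stack([np.random.default_rng(i).permutation(y) for i in range(25)])
        for strategy in ("average", "pooled"):
            batch = _null_r_batch(folds, ys, rc, strategy)
            for i in range(25):
                loop = _null_r(folds, ys[i], rc, strategy)
                for m in ("total", "positive", "negative"):
                    if loop[m] is None:
                        assert not np.isfinite(batch[m][i])
                    else:
                        assert batch[m][i] == pytest.approx(loop[m], abs=1e-12)

    def test_add_one_estimator_never_zero(self, rng):
        x = rng.standard_normal((20, 60))
        y = x[:, 0]
        perm = v.permutation_test(_fm(x), y, v.ModelConfig(n_permutations=20, permutation_seed=1))
        assert all(p >= 1 / 21 for p in perm.empirical_p.values())


class TestImportantNodes:
    def _result(self, freqs, mean_r=None):
        n = len(freqs)
        freqs = np.asarray(freqs, float)
        return v.PredictionResult(
            n_iterations=60,
            predicted={m: np.zeros(60) for m in ("total", "positive", "negative")},
            observed=np.zeros(60),
            r={}, p_parametric={}, valid={}, invalid_reason={},
            selection_frequency=freqs,
            pos_counts=freqs * 60, neg_counts=np.zeros(n),
            mean_selected_r=np.asarray(mean_r if mean_r is not None else np.ones(n)),
            iteration_sets=[],
        )

    def test_strict_threshold_on_58_vs_57_of_60(self):
        res = self._result([58 / 60, 57 / 60, 0.2])
        out = v.important_nodes(res, 0.95)
        assert out["node_id"].tolist() == [1]  # 0.9667 in, 0.95 exactly out

    def test_zero_threshold_keeps_all_ever_selected(self):
        res = self._result([0.5, 0.0, 0.01])
        assert v.important_nodes(res, 1e-9)["node_id"].tolist() == [1, 3]

    def test_sign_labels_follow_mean_training_correlation(self):
        res = self._result([1.0, 1.0], mean_r=[0.4, -0.3])
        out = v.important_nodes(res, 0.95)
        assert out["sign"].tolist() == ["positive", "negative"]

    def test_planted_nodes_become_important_in_noiseless_limit(self):
        spec = v.CohortSpec(
            n_participants=30, n_nodes=20, task_scans=0, effect_nodes=(3, 7, 11),
            effect_size_interaction=2.0, noise_sd=0.0,
            effect_node_correlation=0.97, seed=8,
        )
        t = v.draw_variability_targets(spec)
        beh, gt = v.generate_behavior(spec, t.rest)
        fm = v.interaction_features(t.rest, gt.interdependence)
        res = v.loocv_predict(fm, beh["recovery"].to_numpy())
        imp = set(v.important_nodes(res)["node_id"])
        assert {3, 7, 11} <= imp


class TestNetworkBreakdown:
    def test_manual_tally(self):
        atlas = v.synthetic_atlas(30, seed=0)
        nets = atlas.table.set_index("node_id")["network"]
        nodes = [1, 2, 3, 4, 5]
        out = v.network_breakdown(nodes, atlas)
        manual = pd.Series([nets[k] for k in nodes]).value_counts()
        for _, row in out.iterrows():
            assert row["count"] == manual.get(row["network"], 0)
        assert out["count"].sum() == 5
        assert (out["count"].values[:-1] >= out["count"].values[1:]).all()

    def test_empty_set_all_zero(self):
        atlas = v.synthetic_atlas(10, seed=1)
        out = v.network_breakdown([], atlas)
        assert out["count"].sum() == 0

    def test_unknown_node_rejected(self):
        atlas = v.synthetic_atlas(10, seed=1)
        with pytest.raises(ValueError, match="999"):
            v.network_breakdown([999], atlas)


class TestSubgroupFixedFeatures:
    def test_group_of_four_rejected(self, rng):
        x = rng.standard_normal((10, 4))
        groups = ["high"] * 4 + ["low"] * 6
        with pytest.raises(ValueError, match="at least 5"):
            v.subgroup_fixed_feature_predict(_fm(x), rng.standard_normal(10), groups, [1], [])

    def test_planted_effect_holds_in_both_groups(self):
        spec = v.CohortSpec(
            n_participants=40, n_nodes=20, task_scans=0, effect_nodes=(1, 2, 3, 4),
            effect_size_interaction=2.5, noise_sd=0.5,
            effect_node_correlation=0.95, seed=17,
        )
        t = v.draw_variability_targets(spec)
        beh, gt = v.generate_behavior(spec, t.rest)
        fm = v.interaction_features(t.rest, gt.interdependence)
        out = v.subgroup_fixed_feature_predict(
            fm, beh["recovery"].to_numpy(), beh["group"], [1, 2, 3, 4], []
        )
        assert set(out) == {"high", "low"}
        assert all(s["r"] > 0 for s in out.values())

    def test_noise_nodes_give_no_positive_power_on_average(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((24, 8))
            y = rng.standard_normal(24)
            groups = ["high"] * 12 + ["low"] * 12
            out = v.subgroup_fixed_feature_predict(_fm(x), y, groups, [1, 2], [3])
            rs += [s["r"] for s in out.values()]
        assert np.mean(rs) < 0.15
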