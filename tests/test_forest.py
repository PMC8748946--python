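"""Random-forest fitting, OOB bookkeeping, importance, receptor ranking."""

import numpy as np
import pandas as pd
import pytest

from docksel import (
    RFConfig,
    TableSpec,
    average_importance,
    error_grid,
    gen_table,
    impurity_importance,
    learning_curve,
    permutation_importance,
    rank_receptors,
    rf_fit,
    rf_predict,
    topk_model_eval,
)
from docksel.forest import ImportanceTable

CFG = RFConfig(ntree=60, mtry=5, maxnode=30, seed=0)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    n = 150
    x = pd.DataFrame(
        {
            "signal": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "constant": np.ones(n),
        }
    )
    y = x["signal"].to_numpy() * 3.0 + rng.normal(scale=0.1, size=n)
    return x, y


class TestRfFit:
    def test_constant_target_gives_zero_oob_mse(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 3))
        y = np.full(40, -8.0)
        rf = rf_fit(x, y, RFConfig(ntree=25, mtry=2, maxnode=5, seed=0))
        assert rf.oob_mse == pytest.approx(0.0)
        assert np.allclose(rf.oob_pred[~rf.never_oob], -8.0)

    def test_same_seed_reproducible(self, planted):
        x, y = planted
        a = rf_fit(x, y, CFG)
        b = rf_fit(x, y, CFG)
        assert a.oob_mse == b.oob_mse
        assert np.array_equal(a.in_bag, b.in_bag)
        assert np.allclose(a.oob_pred, b.oob_pred, equal_nan=True)

    def test_strong_signal_beats_target_variance(self, planted):
        x, y = planted
        rf = rf_fit(x, y, RFConfig(ntree=200, mtry=2, maxnode=60, seed=2))
        assert rf.oob_mse < 0.5 * np.var(y)

    def test_oob_mse_recomputable_from_masks(self, planted):
        """Bookkeeping oracle: OOB MSE from stored per-tree masks."""
        x, y = planted
        rf = rf_fit(x, y, CFG)
        matrix = x.to_numpy()
        sums = np.zeros(len(y))
        counts = np.zeros(len(y))
        for t, tree in enumerate(rf.trees):
            oob = ~rf.in_bag[t]
            sums[oob] += tree.predict(matrix[oob])
            counts[oob] += 1
        valid = counts > 0
        recomputed = float(np.mean((sums[valid] / counts[valid] - y[valid]) ** 2))
        assert rf.oob_mse == pytest.approx(recomputed, rel=1e-6)

    def test_mtry_clamped_with_warning(self, planted):
        x, y = planted
        with pytest.warns(UserWarning, match="clamped"):
            rf_fit(x, y, RFConfig(ntree=5, mtry=999, maxnode=10, seed=0))

    def test_forest_prediction_is_tree_mean(self, planted):
        x, y = planted
        rf = rf_fit(x, y, CFG)
        matrix = x.to_numpy()[:5]
        expected = np.mean([t.predict(matrix) for t in rf.trees], axis=0)
        assert np.allclose(rf_predict(rf, matrix), expected, atol=1e-5)


class TestPermutationImportance:
    def test_signal_dominates_noise(self, planted):
        x, y = planted
        rf = rf_fit(x, y, RFConfig(ntree=120, mtry=2, maxnode=40, seed=3))
        table = permutation_importance(rf, x, y)
        series = table.series("scaled")
        assert series["signal"] > 5 * abs(series["noise1"])
        assert series["signal"] > 5 * abs(series["noise2"])

    def test_constant_feature_importance_zero_and_flagged(self, planted):
        x, y = planted
        rf = rf_fit(x, y, CFG)
        with pytest.warns(UserWarning, match="zero per-tree sd"):
            table = permutation_importance(rf, x, y)
        idx = table.features.index("constant")
        assert table.raw_mean[idx] == 0.0
        assert table.unscaled_flags[idx]

    def test_pure_function_of_forest_and_data(self, planted):
        x, y = planted
        rf = rf_fit(x, y, CFG)
        a = permutation_importance(rf, x, y)
        b = permutation_importance(rf, x, y)
        assert np.allclose(a.scaled, b.scaled, equal_nan=True)

    def test_agrees_with_sklearn_permutation_importance_direction(self, planted):
        """Independent cross-check: sklearn's whole-forest permutation
        importance must rank the planted signal first as well."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.inspection import permutation_importance as sk_perm

        x, y = planted
        forest = RandomForestRegressor(
            n_estimators=100, max_features=2, max_leaf_nodes=40, random_state=0
        ).fit(x, y)
        sk = sk_perm(forest, x, y, n_repeats=5, random_state=0)
        rf = rf_fit(x, y, RFConfig(ntree=100, mtry=2, maxnode=40, seed=1))
        ours = permutation_importance(rf, x, y)
        assert x.columns[np.argmax(sk.importances_mean)] == "signal"
        assert ours.features[int(np.argmax(ours.scaled))] == "signal"


class TestImpurityImportance:
    def test_unused_feature_exactly_zero(self, planted):
        x, y = planted
        rf = rf_fit(x, y, CFG)
        table = impurity_importance(rf)
        idx = table.features.index("constant")
        assert table.raw_mean[idx] == 0.0

    def test_single_feature_forest_carries_everything(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(80, 1))
        y = x[:, 0] * 2 + rng.normal(scale=0.1, size=80)
        rf = rf_fit(x, y, RFConfig(ntree=20, mtry=1, maxnode=10, seed=0))
        table = impurity_importance(rf)
        assert table.raw_mean[0] > 0

    def test_matches_sklearn_tree_importances(self, planted):
        """Our node-variance accounting equals sklearn's per-tree importances
        up to sklearn's normalisation."""
        x, y = planted
        rf = rf_fit(x, y, RFConfig(ntree=10, mtry=4, maxnode=20, seed=7))
        ours = impurity_importance(rf).raw_mean
        expected = np.zeros(len(rf.feature_names))
        for tree in rf.trees:
            t = tree.tree_
            unnormalised = tree.feature_importances_ * 1.0
            total = 0.0
            left, right = t.children_left, t.children_right
            internal = left != -1
            w = t.weighted_n_node_samples
            total = (
                w[internal] * t.impurity[internal]
                - w[left[internal]] * t.impurity[left[internal]]
                - w[right[internal]] * t.impurity[right[internal]]
            ).sum() / w[0]
            expected += unnormalised * total
        expected /= len(rf.trees)
        assert np.allclose(ours, expected, atol=1e-10)

    def test_rank_correlates_with_permutation_on_planted_data(self, planted):
        from scipy.stats import spearmanr

        x, y = planted
        rf = rf_fit(x, y, RFConfig(ntree=150, mtry=2, maxnode=40, seed=9))
        imp_imp = impurity_importance(rf).raw_mean
        perm_imp = permutation_importance(rf, x, y).raw_mean
        rho = spearmanr(imp_imp, perm_imp).statistic
        assert rho > 0.5


class TestAverageImportance:
    def test_single_repeat_equals_single_run(self, planted):
        x, y = planted
        averaged = average_importance(x, y, CFG, n_repeats=1, seeds=[CFG.seed])
        rf = rf_fit(x, y, CFG)
        single = permutation_importance(rf, x, y)
        assert np.allclose(averaged["mean"].to_numpy(), single.scaled, equal_nan=True)

    def test_fixed_seed_list_reproducible(self, planted):
        x, y = planted
        a = average_importance(x, y, CFG, n_repeats=3, seeds=[1, 2, 3])
        b = average_importance(x, y, CFG, n_repeats=3, seeds=[1, 2, 3])
        pd.testing.assert_frame_equal(a, b)


class TestRankReceptors:
    def _importance(self, mapping):
        names = list(mapping)
        values = np.array([mapping[n] for n in names], dtype=float)
        return ImportanceTable(names, values, values.copy())

    def test_dominant_receptor_first(self):
        mapping = {}
        for rec, level in (("r1", 1.0), ("r2", 0.1)):
            for term in ("VHD", "ELC", "TOR", "INT"):
                mapping[f"{rec}_{term}"] = level
        mapping["MW"] = 99.0  # descriptors never enter receptor sums
        ranking = rank_receptors(self._importance(mapping), ["r1", "r2"])
        assert ranking.order == ["r1", "r2"]
        assert ranking.sums["r1"] == pytest.approx(4.0)

    def test_all_zero_ties_break_by_id(self):
        mapping = {
            f"{rec}_{term}": 0.0
            for rec in ("zz", "aa", "mm")
            for term in ("VHD", "ELC", "TOR", "INT")
        }
        ranking = rank_receptors(self._importance(mapping), ["zz", "aa", "mm"])
        assert ranking.order == ["aa", "mm", "zz"]

    def test_wrong_feature_count_rejected(self):
        mapping = {"r1_VHD": 1.0, "r1_ELC": 1.0}
        with pytest.raises(ValueError, match="exactly 4"):
            rank_receptors(self._importance(mapping), ["r1"])


class TestErrorGridAndLearningCurve:
    @pytest.fixture(scope="class")
    def table(self):
        return gen_table(TableSpec(n_ligands=80, n_receptors=6, seed=2))[0]

    def test_single_grid_point_and_duplicate_reproducibility(self, table):
        x, y = table.feature_matrix(), table.y
        cfg = RFConfig(ntree=40, mtry=6, maxnode=20, seed=0)
        oob, tst = error_grid(x, y, [6], [20], cfg, seed=5)
        assert oob.shape == (1, 1) and tst.shape == (1, 1)
        oob2, tst2 = error_grid(x, y, [6, 6], [20], cfg, seed=5)
        assert oob2.iloc[0, 0] == oob2.iloc[0, 1] == oob.iloc[0, 0]

    def test_test_mse_flat_in_maxnode_beyond_saturation(self, table):
        x, y = table.feature_matrix(), table.y
        cfg = RFConfig(ntree=60, mtry=8, maxnode=20, seed=0)
        _, tst = error_grid(x, y, [8], [40, 80, 120], cfg, seed=1)
        values = tst[8].to_numpy()
        spread = values.max() - values.min()
        assert spread < 0.5 * values.mean()  # saturated: depth no longer matters

    def test_learning_curve_reproducible(self, table):
        x, y = table.feature_matrix(), table.y
        cfg = RFConfig(ntree=30, mtry=6, maxnode=20, seed=0)
        a = learning_curve(x, y, [0.5, 0.7], repeats=2, config=cfg, seed=4)
        b = learning_curve(x, y, [0.5, 0.7], repeats=2, config=cfg, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_fraction_rejected(self, table):
        x, y = table.feature_matrix(), table.y
        with pytest.raises(ValueError):
            learning_curve(x, y, [0.005], repeats=1, config=CFG, seed=0)


class TestTopKModel:
    def test_feature_count_contract(self, small_table):
        table, _ = small_table
        cfg = RFConfig(ntree=15, mtry=8, maxnode=15, seed=0)
        for k, with_m, expected in ((3, False, 12), (3, True, 20), (5, True, 28)):
            report = topk_model_eval(table, table.receptor_ids, k, with_m, cfg)
            assert report.n_features == expected

    def test_one_forest_per_ligand(self, small_table):
        table, _ = small_table
        cfg = RFConfig(ntree=10, mtry=4, maxnode=10, seed=0)
        report = topk_model_eval(table, table.receptor_ids, 2, False, cfg)
        assert len(report.per_forest_oob_mse) == table.n_ligands
        assert len(report.loo_pred) == table.n_ligands

    def test_constant_target_loo_mse_zero(self):
        table, _ = gen_table(TableSpec(n_ligands=15, n_receptors=3, seed=8))
        import pandas as pd

        from docksel.features import DockingFeatureTable

        const = DockingFeatureTable(
            table.terms, table.scores, pd.Series(-8.0, index=table.ligand_ids),
            table.descriptors,
        )
        cfg = RFConfig(ntree=10, mtry=4, maxnode=10, seed=0)
        report = topk_model_eval(const, const.receptor_ids, 3, False, cfg)
        assert report.metrics.mse == pytest.approx(0.0)
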