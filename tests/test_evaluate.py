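"""Docking scenarios, metrics, enrichment, and the seen/unseen experiment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from docksel import (
    TableSpec,
    cluster_ensemble_eval,
    count_matrix,
    dissimilarity_tensor,
    ensemble_predict,
    enrichment_factor,
    gen_table,
    metrics,
    seen_unseen_experiment,
    single_and_pair_scan,
    ward_cluster,
)
from docksel.dissimilarity import PairMatrix


class TestEnsemblePredict:
    def test_singleton_min_equals_mean_equals_scores(self, small_table):
        table, _ = small_table
        rec = table.receptor_ids[0]
        for scenario in ("min", "mean"):
            pred = ensemble_predict(table, [rec], scenario)
            assert np.allclose(pred.values, table.scores[rec].to_numpy())

    def test_min_and_mean_reduction(self, small_table):
        table, _ = small_table
        subset = table.receptor_ids[:2]
        block = table.scores[subset].to_numpy()
        assert np.allclose(ensemble_predict(table, subset, "min").values, block.min(axis=1))
        assert np.allclose(ensemble_predict(table, subset, "mean").values, block.mean(axis=1))

    def test_matches_brute_force_per_ligand(self, small_table):
        table, _ = small_table
        subset = table.receptor_ids[:3]
        pred = ensemble_predict(table, subset, "min")
        for i, lig in enumerate(table.ligand_ids):
            expected = min(table.scores.loc[lig, r] for r in subset)
            assert pred.values[i] == pytest.approx(expected)

    def test_min_non_increasing_as_ensemble_grows(self, small_table):
        table, _ = small_table
        previous = None
        for size in range(1, table.n_receptors + 1):
            pred = ensemble_predict(table, table.receptor_ids[:size], "min").values
            if previous is not None:
                assert (pred <= previous + 1e-12).all()
            previous = pred

    def test_empty_subset_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ValueError):
            ensemble_predict(table, [], "min")


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([-9.0, -8.0, -7.0, -6.0])
        report = metrics(y, y)
        assert report.mse == 0.0
        assert report.pearson == pytest.approx(1.0)
        assert all(v == 100.0 for v in report.ef.values())

    def test_anticorrelated(self):
        y = np.array([-9.0, -8.0, -7.0, -6.0])
        assert metrics(-y, y).pearson == pytest.approx(-1.0)

    def test_matches_textbook_formulas_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            pred, y = rng.normal(size=n), rng.normal(size=n)
            report = metrics(pred, y)
            assert report.mse == pytest.approx(((pred - y) ** 2).sum() / n)
            assert report.mae == pytest.approx(np.abs(pred - y).sum() / n)
            pc = ((pred - pred.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((pred - pred.mean()) ** 2).sum())
                * np.sqrt(((y - y.mean()) ** 2).sum())
            )
            assert report.pearson == pytest.approx(pc)
            ranks_p = stats.rankdata(pred)
            ranks_y = stats.rankdata(y)
            rc = np.corrcoef(ranks_p, ranks_y)[0, 1]
            assert report.spearman == pytest.approx(rc)

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(1)
        pred, y = rng.normal(size=30), rng.normal(size=30)
        report = metrics(pred, y)
        rank_report = metrics(stats.rankdata(pred), stats.rankdata(y))
        assert report.spearman == pytest.approx(rank_report.pearson)

    def test_zero_variance_correlation_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            report = metrics(np.ones(5), np.arange(5.0))
        assert math.isnan(report.pearson)


class TestEnrichmentFactor:
    def test_identical_rankings_are_100(self):
        y = np.array([-9.0, -8.5, -7.0, -6.0, -5.0])
        for x in (10, 20, 50, 100):
            assert enrichment_factor(y, y * 2 - 1, x) == 100.0

    def test_partial_overlap(self):
        ids = list("ABCDEFGHIJ")
        y_exp = np.arange(10.0)  # top-2 = A, B (most negative first)
        y_calc = np.array([0.0, 5, 1, 9, 8, 7, 6, 4, 3, 2])  # top-2 = A, C
        assert enrichment_factor(y_exp, y_calc, 20, ids=ids) == 50.0

    def test_x_100_always_100(self):
        rng = np.random.default_rng(2)
        assert enrichment_factor(rng.normal(size=9), rng.normal(size=9), 100) == 100.0

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(3)
        y_exp, y_calc = rng.normal(size=25), rng.normal(size=25)
        base = enrichment_factor(y_exp, y_calc, 20)
        assert enrichment_factor(np.exp(y_exp), y_calc, 20) == base
        assert enrichment_factor(y_exp, 3 * y_calc + 7, 20) == base
        assert enrichment_factor(np.arctan(y_exp), np.tanh(y_calc), 20) == base

    def test_floor_of_one_for_tiny_sets(self):
        y = np.array([-2.0, -1.0])
        assert enrichment_factor(y, y, 5) == 100.0  # k = max(1, floor(0.1)) = 1


class TestScan:
    def test_pair_count_and_consistency_with_metrics(self, small_table):
        table, _ = small_table
        scan = single_and_pair_scan(table)
        n = table.n_receptors
        assert scan.n_pairs == n * (n - 1) // 2
        # vectorised frame agrees with the scalar metrics path
        rec = table.receptor_ids[0]
        direct = metrics(
            table.scores[rec].to_numpy(), table.y.to_numpy(), ids=table.ligand_ids
        )
        row = scan.singles["min"].loc[rec]
        assert row["MSE"] == pytest.approx(direct.mse)
        assert row["R_p"] == pytest.approx(direct.pearson)
        assert row["R_s"] == pytest.approx(direct.spearman)
        assert row["EF_20%"] == pytest.approx(direct.ef[20.0])
        pair = f"{table.receptor_ids[0]}+{table.receptor_ids[1]}"
        pred = ensemble_predict(table, table.receptor_ids[:2], "mean")
        direct_pair = metrics(pred.values, table.y.to_numpy(), ids=table.ligand_ids)
        assert scan.pairs["mean"].loc[pair, "MSE"] == pytest.approx(direct_pair.mse)

    def test_three_receptors_three_pairs(self):
        table, _ = gen_table(TableSpec(n_ligands=20, n_receptors=3, seed=3))
        assert single_and_pair_scan(table).n_pairs == 3

    def test_perfect_receptor_identified(self, small_table):
        table, _ = small_table
        import pandas as pd

        scores = table.scores.copy()
        scores["PERF"] = table.y
        from docksel.features import DockingFeatureTable, TERMS

        terms = table.terms.copy()
        for t in TERMS:
            terms[f"PERF_{t}"] = 0.0
        boosted = DockingFeatureTable(terms, scores, table.y, table.descriptors)
        scan = single_and_pair_scan(boosted)
        assert scan.best_single_mse == "PERF"
        assert scan.singles["min"].loc["PERF", "MSE"] == 0.0


class TestSeenUnseen:
    def test_dominant_receptor_always_selected(self, small_table):
        table, _ = small_table
        from docksel.features import DockingFeatureTable, TERMS

        scores = table.scores.copy()
        scores["STAR"] = table.y  # zero error on every subset
        terms = table.terms.copy()
        for t in TERMS:
            terms[f"STAR_{t}"] = 0.0
        boosted = DockingFeatureTable(terms, scores, table.y, table.descriptors)
        result = seen_unseen_experiment(boosted, [0.5], repeats=12, seed=0)
        assert (result.records["best_seen_receptor"] == "STAR").all()
        assert result.selection_frequencies[0.5]["STAR"] == 1.0

    def test_reproducible_and_frequencies_sum_to_one(self, small_table):
        table, _ = small_table
        a = seen_unseen_experiment(table, [0.3, 0.6], repeats=5, seed=9)
        b = seen_unseen_experiment(table, [0.3, 0.6], repeats=5, seed=9)
        assert a.records.equals(b.records)
        for freq in a.selection_frequencies.values():
            assert freq.sum() == pytest.approx(1.0)

    def test_near_tied_receptors_match_exhaustive_split_enumeration(self):
        """With n small, selection frequency follows the exhaustive split law."""
        import pandas as pd

        from docksel.features import DockingFeatureTable, TERMS

        rng = np.random.default_rng(4)
        n = 8
        ligands = [f"L{i}" for i in range(n)]
        y = pd.Series(rng.normal(-8, 1, n), index=ligands)
        scores = pd.DataFrame(
            {
                "r1": y + rng.normal(scale=0.5, size=n),
                "r2": y + rng.normal(scale=0.5, size=n),
            },
            index=ligands,
        )
        terms = pd.DataFrame(
            {f"{r}_{t}": 0.0 for r in scores for t in TERMS}, index=ligands
        )
        table = DockingFeatureTable(terms, scores, y)
        n_seen = 4
        wins = 0
        combos = list(itertools.combinations(range(n), n_seen))
        sq = (scores.to_numpy() - y.to_numpy()[:, None]) ** 2
        for combo in combos:
            seen_mse = sq[list(combo)].mean(axis=0)
            if seen_mse[0] < seen_mse[1] or (seen_mse[0] == seen_mse[1]):
                wins += 1
        expected = wins / len(combos)
        result = seen_unseen_experiment(table, [0.5], repeats=4000, seed=1)
        observed = result.selection_frequencies[0.5]["r1"]
        assert observed == pytest.approx(expected, abs=0.05)

    def test_degenerate_fraction_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ValueError):
            seen_unseen_experiment(table, [0.001], repeats=1, seed=0)


class TestClusterEnsembleEval:
    def _matrix(self, table):
        rng = np.random.default_rng(5)
        n = table.n_receptors
        sym = rng.uniform(0.5, 5, (n, n))
        sym = (sym + sym.T) / 2
        np.fill_diagonal(sym, 0)
        return PairMatrix(sym, table.receptor_ids, kind="T")

    def test_representative_metrics_match_recomposition(self, small_table):
        table, _ = small_table
        matrix = self._matrix(table)
        partitions = {k: ward_cluster(matrix, k) for k in (2, 3)}
        report = cluster_ensemble_eval(table, partitions, matrix, n_random=3, seed=0)
        from docksel.dissimilarity import cluster_representatives

        for k in (2, 3):
            reps = cluster_representatives(partitions[k], matrix)
            pred = ensemble_predict(table, reps, "min")
            direct = metrics(pred.values, table.y.to_numpy(), ids=table.ligand_ids)
            row = report[
                (report["k"] == k)
                & (report["scenario"] == "min")
                & (report["ensemble"] == "representatives")
            ].iloc[0]
            assert row["MSE"] == pytest.approx(direct.mse)

    def test_k_equal_r_uses_all_receptors(self, small_table):
        table, _ = small_table
        matrix = self._matrix(table)
        partitions = {table.n_receptors: ward_cluster(matrix, table.n_receptors)}
        report = cluster_ensemble_eval(table, partitions, matrix, n_random=1, seed=0)
        reps_row = report[report["ensemble"] == "representatives"].iloc[0]
        assert sorted(reps_row["receptors"].split(",")) == sorted(table.receptor_ids)

    def test_seeded_reproducibility(self, small_table):
        table, _ = small_table
        matrix = self._matrix(table)
        partitions = {2: ward_cluster(matrix, 2)}
        a = cluster_ensemble_eval(table, partitions, matrix, n_random=4, seed=3)
        b = cluster_ensemble_eval(table, partitions, matrix, n_random=4, seed=3)
        assert a.equals(b)
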