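"""Docking-without-learning scenarios and their performance metrics.

Ensemble docking aggregates per-receptor docking scores per ligand either
as the average over the receptor subset ("mean" scenario) or as the best
— most negative — score ("min" scenario).  This module evaluates single
receptors, all unordered receptor pairs, cluster-representative ensembles
and random same-size ensembles with the standard metrics (MSE, MAE,
Pearson and Spearman correlations) plus the early-recognition enrichment
factor EF_x%: the percentage of the top x% experimentally ranked ligands
recovered within the top x% of computationally ranked ligands.

The seen/unseen experiment probes how well picking the best single
receptor on a random ligand fraction generalises to the held-out
ligands, against a randomly chosen receptor as baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dissimilarity import ClusterPartition, PairMatrix, cluster_representatives
from .features import DockingFeatureTable

__all__ = [
    "ScenarioPrediction",
    "MetricsReport",
    "SeenUnseenResult",
    "ensemble_predict",
    "metrics",
    "enrichment_factor",
    "single_and_pair_scan",
    "seen_unseen_experiment",
    "cluster_ensemble_eval",
]

SCENARIOS = ("min", "mean")
DEFAULT_EF_LEVELS = (5.0, 20.0, 50.0)


@dataclass
class ScenarioPrediction:
    """Per-ligand ensemble docking prediction for one receptor subset."""

    ligand_ids: list[str]
    values: np.ndarray
    scenario: str
    receptors: list[str]


@dataclass
class MetricsReport:
    """Accuracy and ranking metrics of one prediction vector."""

    mse: float
    mae: float
    pearson: float
    spearman: float
    ef: dict[float, float]

    def as_row(self) -> dict[str, float]:
        row = {"MSE": self.mse, "MAE": self.mae, "R_p": self.pearson, "R_s": self.spearman}
        row.update({f"EF_{level:g}%": value for level, value in self.ef.items()})
        return row


def ensemble_predict(
    table: DockingFeatureTable, receptors: Sequence[str], scenario: str
) -> ScenarioPrediction:
    """Aggregate per-receptor docking scores over a receptor subset.

    "mean": average score; "min": best affinity, i.e. the most negative
    score.  For a singleton subset the two coincide.
    """
    receptors = list(receptors)
    if not receptors:
        raise ValueError("receptor subset must be non-empty")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    block = table.scores[receptors].to_numpy()
    values = block.min(axis=1) if scenario == "min" else block.mean(axis=1)
    return ScenarioPrediction(list(table.ligand_ids), values, scenario, receptors)


def enrichment_factor(
    y_exp: np.ndarray,
    y_calc: np.ndarray,
    x: float,
    ids: Sequence[str] | None = None,
) -> float:
    """EF_x%: overlap between experimental and computed top-x% ligand sets.

    The top set holds the k = max(1, floor(x n / 100)) strongest-affinity
    (most negative) ligands of each ranking; ties break by ligand id so
    the value is deterministic.  Result in percent, in [0, 100].
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    n = len(y_exp)
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if n < 1 or len(y_calc) != n:
        raise ValueError("need equal-length non-empty score vectors")
    ids = np.arange(n).astype(str) if ids is None else np.asarray(ids, dtype=str)
    k = max(1, math.floor(x * n / 100.0))
    top_exp = set(ids[np.lexsort((ids, y_exp))][:k])
    top_calc = set(ids[np.lexsort((ids, y_calc))][:k])
    return 100.0 * len(top_exp & top_calc) / k


def _correlations(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(pred) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined, reported as NaN")
        return float("nan"), float("nan")
    pearson = float(stats.pearsonr(pred, y).statistic)
    spearman = float(stats.spearmanr(pred, y).statistic)
    return pearson, spearman


def metrics(
    pred: np.ndarray,
    y: np.ndarray,
    ef_levels: Iterable[float] = DEFAULT_EF_LEVELS,
    ids: Sequence[str] | None = None,
) -> MetricsReport:
    """MSE, MAE, Pearson, Spearman and EF_x% of a prediction vector."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape or pred.size < 2:
        raise ValueError("pred and y must be equal-length vectors of size >= 2")
    residual = pred - y
    pearson, spearman = _correlations(pred, y)
    ef = {float(x): enrichment_factor(y, pred, x, ids=ids) for x in ef_levels}
    return MetricsReport(
        mse=float(np.mean(residual**2)),
        mae=float(np.mean(np.abs(residual))),
        pearson=pearson,
        spearman=spearman,
        ef=ef,
    )


def _metrics_frame(
    predictions: np.ndarray,
    names: Sequence[str],
    y: np.ndarray,
    ef_levels: Iterable[float],
    ids: Sequence[str],
) -> pd.DataFrame:
    """Metrics for many prediction columns at once (vectorised MSE/MAE/rho)."""
    y = np.asarray(y, dtype=float)
    resid = predictions - y[:, None]
    mse = (resid**2).mean(axis=0)
    mae = np.abs(resid).mean(axis=0)
    yc = y - y.mean()
    pc = predictions - predictions.mean(axis=0)
    denom = np.sqrt((yc**2).sum()) * np.sqrt((pc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = (pc * yc[:, None]).sum(axis=0) / denom
    ranks_y = stats.rankdata(y)
    ranks_p = stats.rankdata(predictions, axis=0)
    ryc = ranks_y - ranks_y.mean()
    rpc = ranks_p - ranks_p.mean(axis=0)
    rdenom = np.sqrt((ryc**2).sum()) * np.sqrt((rpc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        spearman = (rpc * ryc[:, None]).sum(axis=0) / rdenom
    rows = {"MSE": mse, "MAE": mae, "R_p": pearson, "R_s": spearman}
    for level in ef_levels:
        rows[f"EF_{level:g}%"] = [
            enrichment_factor(y, predictions[:, j], level, ids=ids)
            for j in range(predictions.shape[1])
        ]
    return pd.DataFrame(rows, index=list(names))


@dataclass
class ScanResult:
    """Single-receptor and receptor-pair scan reports."""

    singles: dict[str, pd.DataFrame]  # scenario -> per-receptor metrics
    pairs: dict[str, pd.DataFrame]  # scenario -> per-pair metrics
    best_single_mse: str
    worst_single_mse: str
    best_single_pearson: str
    worst_single_pearson: str

    @property
    def n_pairs(self) -> int:
        return len(next(iter(self.pairs.values())))


def single_and_pair_scan(
    table: DockingFeatureTable,
    scenarios: Sequence[str] = SCENARIOS,
    ef_levels: Iterable[float] = DEFAULT_EF_LEVELS,
) -> ScanResult:
    """Evaluate every single receptor and every unordered receptor pair.

    R receptors yield R single-receptor reports (scenario-independent) and
    R(R-1)/2 pair reports per scenario; the best/worst singles by MSE and
    by Pearson correlation are identified.
    """
    if table.n_receptors < 2:
        raise ValueError("need at least two receptors")
    y = table.y.to_numpy()
    ids = table.ligand_ids
    scores = table.scores.to_numpy()
    receptor_ids = table.receptor_ids
    ef_levels = list(ef_levels)
    singles_frame = _metrics_frame(scores, receptor_ids, y, ef_levels, ids)
    singles = {sc: singles_frame.copy() for sc in scenarios}
    pair_index = [
        (i, j) for i in range(len(receptor_ids)) for j in range(i + 1, len(receptor_ids))
    ]
    pair_names = [f"{receptor_ids[i]}+{receptor_ids[j]}" for i, j in pair_index]
    left = scores[:, [i for i, _ in pair_index]]
    right = scores[:, [j for _, j in pair_index]]
    pairs = {}
    for sc in scenarios:
        block = np.minimum(left, right) if sc == "min" else (left + right) / 2.0
        pairs[sc] = _metrics_frame(block, pair_names, y, ef_levels, ids)
    mse_series = singles_frame["MSE"]
    rp_series = singles_frame["R_p"]
    return ScanResult(
        singles=singles,
        pairs=pairs,
        best_single_mse=mse_series.idxmin(),
        worst_single_mse=mse_series.idxmax(),
        best_single_pearson=rp_series.idxmax(),
        worst_single_pearson=rp_series.idxmin(),
    )


@dataclass
class SeenUnseenResult:
    """Outcome of the best-receptor-on-seen-data experiment.

    ``records`` holds one row per (fraction, repeat) with the best-seen
    receptor, its seen and unseen MSE, and the unseen MSE of a random
    receptor; ``selection_frequencies`` maps each seen fraction to the
    per-receptor selection frequency (summing to 1).
    """

    records: pd.DataFrame
    selection_frequencies: dict[float, pd.Series] = field(default_factory=dict)


def seen_unseen_experiment(
    table: DockingFeatureTable,
    fractions: Sequence[float],
    repeats: int,
    seed: int,
) -> SeenUnseenResult:
    """Select the best receptor on a seen ligand fraction, test on the rest.

    Per repeat: ligands are split at random; the receptor with the lowest
    docking MSE on the seen part (ties toward the smallest id) predicts the
    unseen part, compared against one uniformly random receptor on the
    same unseen ligands.  Fully seeded and reproducible.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = table.y.to_numpy()
    scores = table.scores.to_numpy()
    receptor_ids = np.array(table.receptor_ids, dtype=object)
    n = table.n_ligands
    rows = []
    for fraction in fractions:
        if not 0 < fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        n_seen = math.floor(fraction * n)
        if n_seen < 1 or n_seen >= n:
            raise ValueError(f"fraction {fraction} yields an empty seen or unseen set")
        for rep in range(repeats):
            perm = rng.permutation(n)
            seen, unseen = perm[:n_seen], perm[n_seen:]
            seen_mse = ((scores[seen] - y[seen, None]) ** 2).mean(axis=0)
            best = min(zip(seen_mse, receptor_ids), key=lambda t: (t[0], t[1]))[1]
            b = table.receptor_ids.index(best)
            r = int(rng.integers(table.n_receptors))
            rows.append(
                {
                    "fraction": fraction,
                    "repeat": rep,
                    "best_seen_receptor": best,
                    "seen_mse": float(seen_mse[b]),
                    "unseen_mse": float(((scores[unseen, b] - y[unseen]) ** 2).mean()),
                    "random_receptor": receptor_ids[r],
                    "random_unseen_mse": float(((scores[unseen, r] - y[unseen]) ** 2).mean()),
                }
            )
    records = pd.DataFrame(rows)
    frequencies = {}
    for fraction in fractions:
        counts = (
            records.loc[records["fraction"] == fraction, "best_seen_receptor"]
            .value_counts()
            .reindex(table.receptor_ids, fill_value=0)
        )
        frequencies[float(fraction)] = counts / counts.sum()
    return SeenUnseenResult(records, frequencies)


def cluster_ensemble_eval(
    table: DockingFeatureTable,
    partitions: Mapping[int, ClusterPartition],
    matrix: PairMatrix,
    scenarios: Sequence[str] = SCENARIOS,
    n_random: int = 20,
    seed: int = 0,
    ef_levels: Iterable[float] = DEFAULT_EF_LEVELS,
) -> pd.DataFrame:
    """Representative-receptor ensembles per k versus random same-size ones.

    For each partition, the cluster representatives (least summed
    dissimilarity within their cluster) form the ensemble; ``n_random``
    random ensembles of the same size give the reference metric
    distribution.  Returns one row per (k, scenario, ensemble).
    """
    rng = np.random.default_rng(seed)
    y = table.y.to_numpy()
    ids = table.ligand_ids
    ef_levels = list(ef_levels)
    rows = []
    for k, partition in sorted(partitions.items()):
        reps = cluster_representatives(partition, matrix)
        missing = set(reps) - set(table.receptor_ids)
        if missing:
            raise ValueError(f"representatives not in table: {sorted(missing)}")
        for sc in scenarios:
            pred = ensemble_predict(table, reps, sc)
            report = metrics(pred.values, y, ef_levels, ids=ids)
            rows.append(
                {"k": k, "scenario": sc, "ensemble": "representatives",
                 "receptors": ",".join(reps), **report.as_row()}
            )
            for r in range(n_random):
                subset = sorted(rng.choice(table.receptor_ids, size=len(reps), replace=False))
                rpred = ensemble_predict(table, subset, sc)
                rreport = metrics(rpred.values, y, ef_levels, ids=ids)
                rows.append(
                    {"k": k, "scenario": sc, "ensemble": f"random_{r}",
                     "receptors": ",".join(subset), **rreport.as_row()}
                )
    return pd.DataFrame(rows)
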