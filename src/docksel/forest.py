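"""Random-forest rescoring of ensemble-docking energetics.

A bagged ensemble of regression trees predicts experimental binding free
energies from the 4R docking terms (optionally plus 8 molecular
descriptors).  The forest is built tree by tree over explicit bootstrap
samples so that per-tree in-bag masks are retained: out-of-bag (OOB)
error, per-tree OOB permutation importance with its mean/sd scaling, and
importance-based receptor ranking all need that bookkeeping.

Hyperparameters follow the R randomForest conventions: ``ntree`` trees,
``mtry`` candidate features per split, ``maxnode`` terminal nodes per
tree.  Defaults (ntree=500, maxnode=80, mtry=100) reflect the regime in
which OOB and test error become insensitive to tree depth and mtry in the
50-100 range is adequate for a 512-feature docking table.

Importance measures:

* impurity importance — total decrease in node variance attributable to
  splits on a feature, averaged over trees;
* permutation importance — per tree, the increase in OOB MSE when the
  feature column is permuted; scaled by dividing the per-tree mean by the
  per-tree standard deviation (the primary receptor-ranking measure).

Receptors are ranked by the sum of importance over their four term
features; descriptors never enter receptor sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .evaluate import DEFAULT_EF_LEVELS, MetricsReport, metrics
from .features import TERMS, DockingFeatureTable

__all__ = [
    "RFConfig",
    "RFResult",
    "ImportanceTable",
    "ReceptorRanking",
    "rf_fit",
    "rf_predict",
    "error_grid",
    "learning_curve",
    "permutation_importance",
    "impurity_importance",
    "average_importance",
    "rank_receptors",
    "topk_model_eval",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters (randomForest naming)."""

    ntree: int = 500
    mtry: int = 100
    maxnode: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.maxnode < 2:
            raise ValueError("maxnode must be >= 2")


@dataclass
class RFResult:
    """A fitted forest with per-tree bootstrap bookkeeping."""

    trees: list
    in_bag: np.ndarray  # (ntree, n) bool
    oob_pred: np.ndarray  # (n,), NaN where never OOB
    oob_mse: float
    config: RFConfig
    feature_names: list[str]
    n_samples: int

    @property
    def never_oob(self) -> np.ndarray:
        return ~np.isfinite(self.oob_pred)


@dataclass
class ImportanceTable:
    """Per-feature importance values (one measure per column).

    ``scaled`` is the permutation mean divided by the per-tree standard
    deviation; features whose sd is zero keep the raw mean and are listed
    in ``unscaled_flags``.  ``per_tree`` retains the raw per-tree deltas
    (the scaling denominator) when the table came from a permutation run.
    """

    features: list[str]
    raw_mean: np.ndarray
    scaled: np.ndarray
    sd: np.ndarray | None = None
    unscaled_flags: np.ndarray | None = None
    per_tree: np.ndarray | None = None  # (ntree, p)

    def frame(self) -> pd.DataFrame:
        data = {"raw_mean": self.raw_mean, "scaled": self.scaled}
        if self.sd is not None:
            data["sd"] = self.sd
        if self.unscaled_flags is not None:
            data["unscaled"] = self.unscaled_flags
        return pd.DataFrame(data, index=self.features)

    def series(self, measure: str = "scaled") -> pd.Series:
        return pd.Series(
            self.scaled if measure == "scaled" else self.raw_mean, index=self.features
        )


@dataclass
class ReceptorRanking:
    """Receptors ranked by summed importance of their four term features."""

    order: list[str]
    sums: pd.Series
    measure: str = "scaled"


def _tree_predict(tree: DecisionTreeRegressor, x: np.ndarray) -> np.ndarray:
    """Low-overhead prediction path for the fitted tree."""
    try:
        return tree.tree_.predict(np.ascontiguousarray(x, dtype=np.float32)).ravel()
    except Exception:  # pragma: no cover - fallback for API drift
        return tree.predict(x)


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    arr = np.asarray(x, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def rf_fit(x, y, config: RFConfig) -> RFResult:
    """Grow a bagged regression forest with explicit bootstrap bookkeeping.

    Each tree is fit on a bootstrap sample (with replacement, same size);
    at every split ``mtry`` candidate features are drawn (clamped to the
    number of columns with a warning, as R randomForest does) and the tree
    is capped at ``maxnode`` leaves.  The OOB prediction of a sample is
    the mean over trees whose bootstrap excluded it; samples in every
    bootstrap are flagged and excluded from the OOB MSE.
    """
    matrix, names = _as_matrix(x)
    target = np.asarray(y, dtype=float)
    n, p = matrix.shape
    if target.shape != (n,):
        raise ValueError("y must match the number of rows of X")
    if not np.isfinite(matrix).all() or not np.isfinite(target).all():
        raise ValueError("X and y must be finite (no missing cells)")
    mtry = config.mtry
    if mtry > p:
        warnings.warn(f"mtry={mtry} exceeds {p} features; clamped to {p}")
        mtry = p
    rng = np.random.default_rng(config.seed)
    trees = []
    in_bag = np.zeros((config.ntree, n), dtype=bool)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    x32 = np.ascontiguousarray(matrix, dtype=np.float32)
    for t in range(config.ntree):
        idx = rng.integers(0, n, n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        tree = DecisionTreeRegressor(
            max_features=mtry, max_leaf_nodes=config.maxnode, random_state=tree_seed
        )
        tree.fit(matrix[idx], target[idx])
        trees.append(tree)
        in_bag[t, idx] = True
        oob = ~in_bag[t]
        if oob.any():
            oob_sum[oob] += _tree_predict(tree, x32[oob])
            oob_count[oob] += 1
    never = oob_count == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} sample(s) never out-of-bag; excluded from OOB MSE"
        )
    with np.errstate(invalid="ignore"):
        oob_pred = np.where(never, np.nan, oob_sum / np.maximum(oob_count, 1))
    valid = ~never
    oob_mse = float(np.mean((oob_pred[valid] - target[valid]) ** 2))
    return RFResult(trees, in_bag, oob_pred, oob_mse, config, names, n)


def rf_predict(rf: RFResult, x) -> np.ndarray:
    """Forest prediction: mean over all trees."""
    matrix, _ = _as_matrix(x)
    x32 = np.ascontiguousarray(matrix, dtype=np.float32)
    total = np.zeros(matrix.shape[0])
    for tree in rf.trees:
        total += _tree_predict(tree, x32)
    return total / len(rf.trees)


def permutation_importance(rf: RFResult, x, y) -> ImportanceTable:
    """Per-tree OOB permutation importance, scaled by the per-tree sd.

    For tree t and feature f, the delta is the MSE of the tree on its OOB
    samples with column f permuted minus the unpermuted MSE; the scaled
    importance of f is mean_t(delta) / sd_t(delta).  Permutations are
    seeded per (forest seed, tree index, feature index), so the table is
    a pure function of (forest, data).  Features with zero sd keep their
    raw mean, flagged in ``unscaled_flags``.
    """
    matrix, names = _as_matrix(x)
    target = np.asarray(y, dtype=float)
    ntree, p = len(rf.trees), matrix.shape[1]
    deltas = np.full((ntree, p), np.nan)
    for t, tree in enumerate(rf.trees):
        oob = ~rf.in_bag[t]
        if not oob.any():
            continue
        xo = np.ascontiguousarray(matrix[oob], dtype=np.float32)
        yo = target[oob]
        base_mse = float(np.mean((_tree_predict(tree, xo) - yo) ** 2))
        for f in range(p):
            rng = np.random.default_rng(
                np.random.SeedSequence([rf.config.seed & 0x7FFFFFFF, t, f])
            )
            original = xo[:, f].copy()
            xo[:, f] = original[rng.permutation(len(original))]
            perm_mse = float(np.mean((_tree_predict(tree, xo) - yo) ** 2))
            xo[:, f] = original
            deltas[t, f] = perm_mse - base_mse
    raw_mean = np.nanmean(deltas, axis=0)
    sd = np.nanstd(deltas, axis=0, ddof=1)
    flags = sd == 0
    if flags.any():
        warnings.warn(
            f"{int(flags.sum())} feature(s) have zero per-tree sd; reported unscaled"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(flags, raw_mean, raw_mean / np.where(flags, 1.0, sd))
    return ImportanceTable(names, raw_mean, scaled, sd, flags, deltas)


def impurity_importance(rf: RFResult) -> ImportanceTable:
    """Mean decrease of node impurity (variance) per feature, over trees.

    For each internal node splitting on feature f, the weighted impurity
    of the node minus that of its children accrues to f; per tree the sum
    is normalised by the root weight, then averaged over the forest.  A
    feature never split on scores exactly 0.
    """
    p = len(rf.feature_names)
    total = np.zeros(p)
    for tree in rf.trees:
        t = tree.tree_
        left, right = t.children_left, t.children_right
        internal = left != -1
        w = t.weighted_n_node_samples
        imp = t.impurity
        decrease = (
            w[internal] * imp[internal]
            - w[left[internal]] * imp[left[internal]]
            - w[right[internal]] * imp[right[internal]]
        )
        per_tree = np.zeros(p)
        np.add.at(per_tree, t.feature[internal], decrease)
        total += per_tree / w[0]
    mean = total / len(rf.trees)
    return ImportanceTable(list(rf.feature_names), mean, mean.copy())


def average_importance(
    x,
    y,
    config: RFConfig,
    n_repeats: int = 10,
    seeds: Sequence[int] | None = None,
    measure: str = "permutation",
) -> pd.DataFrame:
    """Importance averaged over independently seeded forests.

    Returns a frame with per-feature mean and standard deviation of the
    chosen measure ("permutation" scaled values or "impurity") across
    ``n_repeats`` forests differing only in their random seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    values = []
    names = None
    for seed in seeds:
        rf = rf_fit(x, y, replace(config, seed=int(seed)))
        table = (
            impurity_importance(rf)
            if measure == "impurity"
            else permutation_importance(rf, x, y)
        )
        names = table.features
        values.append(table.scaled)
    stack = np.array(values)
    return pd.DataFrame(
        {
            "mean": stack.mean(axis=0),
            "sd": stack.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(stack.shape[1]),
        },
        index=names,
    )


def rank_receptors(
    importance: ImportanceTable | pd.Series,
    receptor_ids: Sequence[str],
    measure: str = "scaled",
) -> ReceptorRanking:
    """Rank receptors by the summed importance of their 4 term features.

    Molecular descriptors are excluded from the sums; a receptor whose
    term features are not exactly the four expected ones is an error.
    Ties break toward the smallest receptor id.
    """
    series = (
        importance.series(measure)
        if isinstance(importance, ImportanceTable)
        else importance
    )
    sums = {}
    for rec in receptor_ids:
        cols = [f"{rec}_{t}" for t in TERMS]
        present = [c for c in cols if c in series.index]
        if len(present) != 4:
            raise ValueError(
                f"receptor {rec}: expected exactly 4 term features, found {len(present)}"
            )
        sums[rec] = float(series[cols].sum())
    ordered = sorted(sums, key=lambda r: (-sums[r], r))
    return ReceptorRanking(ordered, pd.Series(sums).loc[ordered], measure)


def error_grid(
    x,
    y,
    mtry_values: Sequence[int],
    maxnode_values: Sequence[int],
    config: RFConfig,
    split_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OOB and test MSE surfaces over an (mtry, maxnode) grid.

    One forest per grid point on a single seeded train/test split (default
    80/20).  The forest seed at each point derives from (seed, mtry,
    maxnode), so duplicated grid points reproduce identical values.
    Returns (oob, test) frames indexed by maxnode with mtry columns.
    """
    if not mtry_values or not maxnode_values:
        raise ValueError("grids must be non-empty")
    matrix, _ = _as_matrix(x)
    target = np.asarray(y, dtype=float)
    n = matrix.shape[0]
    perm = np.random.default_rng(seed).permutation(n)
    n_train = math.floor(split_fraction * n)
    if n_train < 2 or n_train >= n:
        raise ValueError("degenerate train/test split")
    train, test = perm[:n_train], perm[n_train:]
    oob = pd.DataFrame(index=list(maxnode_values), columns=list(mtry_values), dtype=float)
    tst = oob.copy()
    for maxnode in maxnode_values:
        for mtry in mtry_values:
            point_seed = int(
                np.random.SeedSequence([seed & 0x7FFFFFFF, mtry, maxnode]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            cfg = replace(config, mtry=mtry, maxnode=maxnode, seed=point_seed)
            rf = rf_fit(matrix[train], target[train], cfg)
            pred = rf_predict(rf, matrix[test])
            oob.loc[maxnode, mtry] = rf.oob_mse
            tst.loc[maxnode, mtry] = float(np.mean((pred - target[test]) ** 2))
    return oob, tst


def learning_curve(
    x,
    y,
    train_fractions: Sequence[float],
    repeats: int,
    config: RFConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """OOB and test MSE distributions versus training-set size.

    For every train fraction and repeat the ligand set is split at random
    (seeded per (seed, fraction, repeat)), a forest is fit on the train
    part, and its OOB MSE plus the test MSE are recorded.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    matrix, _ = _as_matrix(x)
    target = np.asarray(y, dtype=float)
    n = matrix.shape[0]
    rows = []
    for fraction in train_fractions:
        if not 0 < fraction < 1:
            raise ValueError("train fractions must lie in (0, 1)")
        n_train = math.floor(fraction * n)
        if n_train < 2 or n_train >= n:
            raise ValueError(f"fraction {fraction} gives a degenerate split")
        for rep in range(repeats):
            split_seed = np.random.SeedSequence(
                [seed & 0x7FFFFFFF, int(round(fraction * 10**6)), rep]
            )
            rng = np.random.default_rng(split_seed)
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
            rf = rf_fit(matrix[train], target[train], cfg)
            pred = rf_predict(rf, matrix[test])
            rows.append(
                {
                    "train_fraction": fraction,
                    "repeat": rep,
                    "oob_mse": rf.oob_mse,
                    "test_mse": float(np.mean((pred - target[test]) ** 2)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TopKReport:
    """Leave-one-out evaluation of a top-k receptor forest model."""

    receptors: list[str]
    include_descriptors: bool
    metrics: MetricsReport
    loo_pred: pd.Series
    per_forest_oob_mse: pd.Series
    per_ligand_sq_error: pd.Series
    n_features: int


def topk_model_eval(
    table: DockingFeatureTable,
    ranking: ReceptorRanking | Sequence[str],
    k: int,
    include_descriptors: bool,
    config: RFConfig,
    ef_levels: Iterable[float] = DEFAULT_EF_LEVELS,
) -> TopKReport:
    """Leave-one-out metrics of a forest on the top-k receptors' features.

    One forest per ligand is trained on all other ligands using the 4k
    term features of the k most important receptors (+8 descriptors when
    requested); the held-out predictions are pooled into MSE/MAE/rho/EF.
    Per-forest OOB MSE and per-ligand squared errors are retained.
    """
    order = ranking.order if isinstance(ranking, ReceptorRanking) else list(ranking)
    if k > len(order):
        raise ValueError("k exceeds the number of ranked receptors")
    top = order[:k]
    x = table.feature_matrix(top, include_descriptors=include_descriptors)
    expected = 4 * k + (8 if include_descriptors else 0)
    assert x.shape[1] == expected, "feature-count contract 4k (+8) violated"
    matrix = x.to_numpy(dtype=float)
    target = table.y.to_numpy()
    n = len(target)
    preds = np.empty(n)
    oob_mses = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        loo_seed = int(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, i]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        rf = rf_fit(matrix[keep], target[keep], replace(config, seed=loo_seed))
        preds[i] = rf_predict(rf, matrix[i : i + 1])[0]
        oob_mses[i] = rf.oob_mse
    report = metrics(preds, target, ef_levels, ids=table.ligand_ids)
    index = pd.Index(table.ligand_ids, name="ligand")
    return TopKReport(
        receptors=top,
        include_descriptors=include_descriptors,
        metrics=report,
        loo_pred=pd.Series(preds, index=index),
        per_forest_oob_mse=pd.Series(oob_mses, index=index),
        per_ligand_sq_error=pd.Series((preds - target) ** 2, index=index),
        n_features=expected,
    )
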