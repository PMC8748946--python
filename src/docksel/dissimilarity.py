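"""Per-residue dissimilarity tensor and its reductions.

Instead of a single all-residues-at-once RMSD, every binding-site residue
contributes its own RMSD between each pair of aligned receptor
conformations, giving a tensor D of shape (n, n, K).  Two reductions
summarise D per receptor pair: T sums per-residue RMSDs and N counts
residues whose RMSD exceeds a cutoff (2 angstrom by default, the classic
structural-identity threshold).  Ward hierarchical clustering on T or N,
representative extraction and heterogeneity diagnostics support
cluster-based ensemble shrinking for comparison with the graph-based
redundancy removal.

All comparisons use the common frame of the aligned ensemble — there is
no per-residue re-fitting, so rigid differences between residues are
retained.  Atom correspondence per residue is the intersection of heavy
atom names over all members, sorted by name; side-chain label symmetry
(e.g. PHE CD1/CD2) is NOT corrected for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .pocket import ReceptorEnsemble, ResidueKey

__all__ = [
    "DissimilarityTensor",
    "PairMatrix",
    "ClusterPartition",
    "dissimilarity_tensor",
    "total_matrix",
    "count_matrix",
    "ward_cluster",
    "cluster_representatives",
    "max_intracluster",
]


@dataclass
class DissimilarityTensor:
    """n x n x K tensor of per-residue RMSD values (angstrom)."""

    values: np.ndarray
    ids: list[str]
    residue_keys: list[ResidueKey]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError("tensor must be n x n x K")
        if v.shape[0] != len(self.ids) or v.shape[2] != len(self.residue_keys):
            raise ValueError("tensor dimensions do not match id/residue lists")
        if (v < 0).any():
            raise ValueError("dissimilarities must be non-negative")

    def save(self, prefix: str | Path) -> None:
        """Write the tensor (.npz) with a JSON index sidecar."""
        import json

        prefix = Path(prefix)
        np.savez_compressed(prefix.with_suffix(".npz"), values=self.values)
        sidecar = {
            "ids": self.ids,
            "residues": [list(k) for k in self.residue_keys],
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class PairMatrix:
    """Symmetric zero-diagonal receptor-pair matrix of kind T, N or A."""

    values: np.ndarray
    ids: list[str]
    kind: str
    cutoff: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix must be square over the id list")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if np.diagonal(v).any():
            raise ValueError("matrix diagonal must be zero")
        if self.kind not in ("T", "N", "A"):
            raise ValueError("kind must be one of T, N, A")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str, cutoff: float | None = None) -> "PairMatrix":
        frame = pd.read_csv(path, index_col=0)
        frame.columns = frame.columns.astype(str)
        frame.index = frame.index.astype(str)
        return cls(frame.to_numpy(), list(frame.index), kind, cutoff)


@dataclass
class ClusterPartition:
    """A flat k-cluster partition cut from a Ward merge tree."""

    k: int
    labels: np.ndarray
    ids: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != (len(self.ids),):
            raise ValueError("one label per id required")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("labels must cover 0..k-1 with no empty cluster")

    def members(self, cluster: int) -> list[str]:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster]


def _matched_atom_names(ens: ReceptorEnsemble) -> dict[ResidueKey, list[str]]:
    names: dict[ResidueKey, list[str]] = {}
    for key in ens.site.keys:
        common = set(ens.members[0].atom_names(key))
        for m in ens.members[1:]:
            common &= set(m.atom_names(key))
        if not common:
            raise ValueError(f"residue {key}: no heavy atom shared by all members")
        for m in ens.members:
            lost = set(m.atom_names(key)) - common
            if lost:
                warnings.warn(
                    f"residue {key}: member {m.id} loses atoms {sorted(lost)} "
                    "from the common correspondence"
                )
        names[key] = sorted(common)
    return names


def dissimilarity_tensor(ens: ReceptorEnsemble) -> DissimilarityTensor:
    """Per-residue heavy-atom RMSD between every pair of members.

    Requires an aligned ensemble (common frame); RMSD is computed over the
    matched atoms of each residue with no per-residue re-fitting, so the
    tensor is symmetric with a zero diagonal slice.
    """
    if not ens.aligned:
        raise ValueError("ensemble must be superposed (aligned=True) first")
    if len(ens) < 2:
        raise ValueError("need at least two members")
    matched = _matched_atom_names(ens)
    n, big_k = len(ens), len(ens.site.keys)
    values = np.zeros((n, n, big_k))
    for k_idx, key in enumerate(ens.site.keys):
        names = matched[key]
        stack = np.array([m.residue_coords(key, names) for m in ens.members])  # (n, m, 3)
        diff = stack[:, None, :, :] - stack[None, :, :, :]
        values[:, :, k_idx] = np.sqrt((diff**2).sum(axis=3).mean(axis=2))
    return DissimilarityTensor(values, ens.ids, list(ens.site.keys))


def total_matrix(tensor: DissimilarityTensor) -> PairMatrix:
    """T_ij: summed per-residue RMSD over all site residues."""
    return PairMatrix(tensor.values.sum(axis=2), list(tensor.ids), kind="T")


def count_matrix(tensor: DissimilarityTensor, cutoff: float = 2.0) -> PairMatrix:
    """N_ij: number of residues with RMSD strictly above the cutoff.

    The comparison is strict (Heaviside with theta(0) = 0): a residue
    sitting exactly at the cutoff is not counted, so a pair with N = 0 is
    redundant under the downstream criterion.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    counts = (tensor.values > cutoff).sum(axis=2).astype(int)
    return PairMatrix(counts, list(tensor.ids), kind="N", cutoff=cutoff)


def ward_cluster(matrix: PairMatrix, k: int) -> ClusterPartition:
    """Cut a Ward-linkage merge tree of the pair matrix into k clusters.

    The matrix is treated as a precomputed (possibly non-Euclidean)
    distance matrix; the Lance-Williams Ward update rule is applied as
    implemented by scipy's ``linkage`` for determinism.
    """
    n = len(matrix.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    condensed = squareform(np.asarray(matrix.values, dtype=float), checks=False)
    merge = linkage(condensed, method="ward")
    labels_raw = cut_tree(merge, n_clusters=k).ravel()
    # relabel to 0..k-1 in order of first appearance for stable output
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(labels_raw):
        remap.setdefault(int(lab), len(remap))
        labels[i] = remap[int(lab)]
    return ClusterPartition(k=k, labels=labels, ids=list(matrix.ids), linkage=merge)


def cluster_representatives(partition: ClusterPartition, matrix: PairMatrix) -> list[str]:
    """Per cluster, the member with least summed dissimilarity to the rest.

    Ties break toward the lexicographically smallest member id.  Returns
    one id per cluster, ordered by cluster index.
    """
    if partition.ids != matrix.ids:
        raise ValueError("partition and matrix must share the same id order")
    values = np.asarray(matrix.values, dtype=float)
    index = {rid: i for i, rid in enumerate(matrix.ids)}
    reps = []
    for c in range(partition.k):
        members = partition.members(c)
        rows = [index[m] for m in members]
        sums = values[np.ix_(rows, rows)].sum(axis=1)
        best = min(zip(sums, members), key=lambda t: (t[0], t[1]))
        reps.append(best[1])
    return reps


def max_intracluster(partition: ClusterPartition, matrix: PairMatrix) -> list[float]:
    """Per-cluster maximum pairwise dissimilarity (0 for singletons)."""
    if partition.ids != matrix.ids:
        raise ValueError("partition and matrix must share the same id order")
    values = np.asarray(matrix.values, dtype=float)
    index = {rid: i for i, rid in enumerate(matrix.ids)}
    out = []
    for c in range(partition.k):
        rows = [index[m] for m in partition.members(c)]
        block = values[np.ix_(rows, rows)]
        out.append(float(block.max()) if len(rows) > 1 else 0.0)
    return out
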