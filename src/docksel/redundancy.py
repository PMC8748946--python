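"""Graph-based redundancy removal for receptor ensembles.

Two conformations are redundant when no binding-site residue differs by
more than the RMSD cutoff (N_ij = 0).  Those pairs form the edges of the
redundancy graph; a greedy procedure repeatedly takes the currently
highest-degree node as a non-redundant representative and deletes its
closed neighborhood, then keeps every surviving isolated node.  The output
is always an independent dominating set of the graph: selected receptors
are pairwise non-redundant and every eliminated receptor is redundant with
its recorded representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .dissimilarity import PairMatrix

__all__ = [
    "RedundancyGraph",
    "SelectionResult",
    "build_adjacency",
    "select_nonredundant",
    "validate_selection",
]


@dataclass
class RedundancyGraph:
    """Undirected redundancy graph: edge <=> pair of identical receptors."""

    ids: list[str]
    adjacency: np.ndarray  # boolean, symmetric, traceless

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.ids), len(self.ids)):
            raise ValueError("adjacency must be square over the id list")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency must be traceless (no self-loops)")
        self.adjacency = a

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def neighbors(self, node: str) -> list[str]:
        i = self.ids.index(node)
        return [self.ids[j] for j in np.flatnonzero(self.adjacency[i])]

    def to_pair_matrix(self) -> PairMatrix:
        return PairMatrix(self.adjacency.astype(int), list(self.ids), kind="A")

    def write_edge_list(self, path: str | Path) -> None:
        lines = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if self.adjacency[i, j]:
                    lines.append(f"{self.ids[i]}\t{self.ids[j]}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class SelectionResult:
    """Outcome of the greedy max-degree elimination.

    ``selected`` lists the non-redundant representatives in the order they
    were chosen (isolated survivors appended last, sorted by id);
    ``eliminated`` maps every removed receptor to the representative whose
    closed neighborhood deleted it; ``trace`` records (chosen id, degree at
    the time of choice) per iteration.
    """

    selected: list[str]
    eliminated: dict[str, str]
    trace: list[tuple[str, int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected": self.selected,
                    "eliminated": self.eliminated,
                    "trace": [[node, deg] for node, deg in self.trace],
                },
                indent=2,
            )
        )


def build_adjacency(count: PairMatrix) -> RedundancyGraph:
    """Adjacency from the residue-count matrix: edge iff N_ij = 0, i != j."""
    if count.kind != "N":
        raise ValueError("adjacency is built from a count (N) matrix")
    values = np.asarray(count.values)
    adjacency = (values == 0) & ~np.eye(len(count.ids), dtype=bool)
    return RedundancyGraph(list(count.ids), adjacency)


def select_nonredundant(
    graph: RedundancyGraph,
    resolution: Mapping[str, float] | None = None,
) -> SelectionResult:
    """Greedy maximum-degree selection of a non-redundant receptor set.

    At each step the node of maximum degree in the *current* graph is
    selected and its closed neighborhood removed; when no edges remain all
    surviving isolated nodes are selected too.  Degree ties break toward
    the lexicographically smallest id, or — when a ``resolution`` map is
    supplied — toward the best (lowest) crystallographic resolution first.
    Node order of the input does not affect the result: ids are sorted
    internally.
    """
    order = np.argsort(np.array(graph.ids, dtype=object))
    ids = [graph.ids[i] for i in order]
    adj = graph.adjacency[np.ix_(order, order)].copy()
    alive = np.ones(len(ids), dtype=bool)

    def tie_key(i: int) -> tuple:
        if resolution is not None:
            return (resolution.get(ids[i], np.inf), ids[i])
        return (ids[i],)

    selected: list[str] = []
    eliminated: dict[str, str] = {}
    trace: list[tuple[str, int]] = []
    while True:
        degrees = np.where(alive, adj[:, alive].sum(axis=1), -1)
        max_deg = degrees.max(initial=-1)
        if max_deg <= 0:
            break
        candidates = np.flatnonzero(degrees == max_deg)
        chosen = min(candidates, key=tie_key)
        selected.append(ids[chosen])
        trace.append((ids[chosen], int(max_deg)))
        neighborhood = np.flatnonzero(adj[chosen] & alive)
        for j in neighborhood:
            eliminated[ids[j]] = ids[chosen]
        alive[chosen] = False
        alive[neighborhood] = False
    survivors = sorted(ids[i] for i in np.flatnonzero(alive))
    for node in survivors:
        trace.append((node, 0))
    return SelectionResult(selected + survivors, eliminated, trace)


def validate_selection(graph: RedundancyGraph, result: SelectionResult) -> list[str]:
    """Check the independent-dominating-set contract; return violations.

    An empty list means: selected and eliminated partition the nodes, no
    edge joins two selected nodes (independence), and every eliminated
    node is adjacent to its recorded representative (domination).
    """
    violations = []
    nodes = set(graph.ids)
    sel = set(result.selected)
    elim = set(result.eliminated)
    if sel & elim:
        violations.append(f"overlap between selected and eliminated: {sorted(sel & elim)}")
    if sel | elim != nodes:
        missing = nodes - (sel | elim)
        extra = (sel | elim) - nodes
        if missing:
            violations.append(f"nodes unaccounted for: {sorted(missing)}")
        if extra:
            violations.append(f"unknown nodes in result: {sorted(extra)}")
    index = {rid: i for i, rid in enumerate(graph.ids)}
    for a in result.selected:
        for b in result.selected:
            if a < b and graph.adjacency[index[a], index[b]]:
                violations.append(f"independence violated: edge between selected {a} and {b}")
    for node, rep in result.eliminated.items():
        if rep not in sel:
            violations.append(f"domination violated: representative {rep} of {node} not selected")
        elif not graph.adjacency[index[node], index[rep]]:
            violations.append(f"domination violated: {node} not adjacent to representative {rep}")
    return violations
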