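"""Synthetic receptor ensembles and docking feature tables with ground truth.

Every pipeline stage can be exercised against planted truth:

* :func:`gen_ensemble` builds an aligned receptor ensemble whose members
  fall into redundancy groups.  Members of one group are atomic-jitter
  copies of a group base conformation (per-residue RMSD far below the
  redundancy cutoff); different groups have a set of binding-site residues
  displaced by more than the cutoff, so the redundancy graph is exactly a
  disjoint union of cliques, one per group.

* :func:`gen_table` builds a ligand x receptor docking feature table in
  which a known subset S of receptors carries the affinity signal: their
  term features and total scores are linear in a latent true binding free
  energy, while decoy receptors contribute independent noise.  The
  experimental target is the latent energy plus Gaussian noise, so the
  noise variance is a known floor for any regressor's error.

The generated objects use the same containers the real pipeline reads
(:class:`~docksel.pocket.ReceptorEnsemble`,
:class:`~docksel.features.DockingFeatureTable`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DESCRIPTOR_NAMES, DockingFeatureTable
from .pocket import BindingSiteDefinition, ReceptorConformation, ReceptorEnsemble

__all__ = [
    "EnsembleSpec",
    "TableSpec",
    "TableGroundTruth",
    "gen_ensemble",
    "gen_table",
]

#: AutoDock-style per-rotatable-bond torsional penalty (kcal/mol).
TORSION_PENALTY = 0.2983


@dataclass(frozen=True)
class EnsembleSpec:
    """Planted redundancy structure for a synthetic receptor ensemble.

    ``group_sizes`` partitions the receptors into redundancy groups;
    ``sigma_in`` is the isotropic per-coordinate atomic jitter within a
    group (angstrom) and ``displacement`` the rigid shift applied to
    ``displaced_residues`` binding-site residues between groups.  The
    margin check requires the expected within-group per-residue RMSD
    (sigma_in * sqrt(6) for a jittered pair) to stay below the cutoff with
    a 5x safety factor, and the displacement to clear the cutoff by the
    same jitter margin, so group recovery is guaranteed by construction.
    """

    group_sizes: tuple[int, ...] = (3, 3)
    n_residues: int = 8
    atoms_per_residue: int = 4
    sigma_in: float = 0.05
    displaced_residues: int = 2
    displacement: float = 5.0
    cutoff: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.n_residues < 1 or self.atoms_per_residue < 1:
            raise ValueError("need at least one residue and one atom per residue")
        if not 1 <= self.displaced_residues <= self.n_residues:
            raise ValueError("displaced_residues must be in [1, n_residues]")
        if self.sigma_in < 0:
            raise ValueError("sigma_in must be non-negative")
        jitter_rmsd = self.sigma_in * math.sqrt(6.0)
        if jitter_rmsd * 5.0 >= self.cutoff:
            raise ValueError(
                "sigma_in too large: expected within-group RMSD "
                f"{jitter_rmsd:.3f} A must clear the cutoff {self.cutoff} A 5-fold"
            )
        if self.displacement - 5.0 * jitter_rmsd <= self.cutoff:
            raise ValueError("displacement must exceed the cutoff with margin")

    @property
    def n_receptors(self) -> int:
        return sum(self.group_sizes)


def gen_ensemble(spec: EnsembleSpec) -> tuple[ReceptorEnsemble, dict[str, int]]:
    """Generate an aligned ensemble with planted redundancy groups.

    Returns the ensemble and the ground-truth map member id -> group
    index.  Member ids are ``G<g>M<m>``; residues sit on chain "A" with
    keys "1".."K".
    """
    rng = np.random.default_rng(spec.seed)
    atom_names = [f"C{i+1}" for i in range(spec.atoms_per_residue)]
    # base conformation: residues strung 6 A apart, atoms jittered around
    # each residue center so per-residue RMSD is well defined
    base = np.empty((spec.n_residues, spec.atoms_per_residue, 3))
    for k in range(spec.n_residues):
        center = np.array([0.0, 6.0 * k, 0.0])
        base[k] = center + rng.normal(scale=1.0, size=(spec.atoms_per_residue, 3))
    site = BindingSiteDefinition(
        tuple(("A", str(k + 1), None) for k in range(spec.n_residues))
    )
    members = []
    groups: dict[str, int] = {}
    for g, size in enumerate(spec.group_sizes):
        group_base = base.copy()
        group_base[: spec.displaced_residues] += np.array([g * spec.displacement, 0.0, 0.0])
        for m in range(size):
            coords_arr = group_base + rng.normal(
                scale=spec.sigma_in, size=group_base.shape
            )
            member_id = f"G{g:02d}M{m:02d}"
            coords = {
                ("A", str(k + 1)): [
                    (atom_names[a], coords_arr[k, a].copy())
                    for a in range(spec.atoms_per_residue)
                ]
                for k in range(spec.n_residues)
            }
            members.append(ReceptorConformation(member_id, coords))
            groups[member_id] = g
    return ReceptorEnsemble(site, members, aligned=True), groups


@dataclass(frozen=True)
class TableSpec:
    """Planted-signal docking feature table specification.

    ``n_informative`` receptors (the set S) carry the affinity signal:
    their term features are linear in the latent true binding free energy
    dg_true ~ U(dg_range) with per-feature Gaussian noise
    ``feature_noise_sd`` and slopes ``coefficients`` (per term), and their
    total scores track dg_true with noise ``score_noise_sd``.  The
    experimental target is dg_true + N(0, noise_sd^2), so ``noise_sd**2``
    is the irreducible error floor.  Decoy receptors draw all features and
    scores independently of dg_true.  TOR is a per-ligand torsional
    penalty (0.2983 kcal/mol per rotatable bond) shared across receptors,
    matching the docking convention.
    """

    n_ligands: int = 200
    n_receptors: int = 30
    n_informative: int = 3
    coefficients: dict = field(
        default_factory=lambda: {"VHD": 0.55, "ELC": 0.30, "INT": 0.15, "TOR": 0.0}
    )
    noise_sd: float = 0.8
    feature_noise_sd: float = 0.25
    score_noise_sd: float = 0.4
    dg_range: tuple[float, float] = (-12.0, -6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 2 or self.n_receptors < 1:
            raise ValueError("need >= 2 ligands and >= 1 receptor")
        if not 1 <= self.n_informative <= self.n_receptors:
            raise ValueError("informative set must be a non-empty receptor subset")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


@dataclass
class TableGroundTruth:
    """Planted truth behind a synthetic feature table."""

    informative: list[str]
    dg_true: pd.Series
    noise_sd: float
    population_r2: float

    @property
    def noise_variance(self) -> float:
        return self.noise_sd**2


_TERM_INTERCEPTS = {"VHD": -2.0, "ELC": -0.3, "INT": -0.5}
_DECOY_TERMS = {"VHD": (-6.5, 1.2), "ELC": (-0.4, 0.3), "INT": (-0.6, 0.4)}


def gen_table(spec: TableSpec) -> tuple[DockingFeatureTable, TableGroundTruth]:
    """Generate a docking feature table with a planted informative set."""
    rng = np.random.default_rng(spec.seed)
    ligand_ids = [f"L{i:03d}" for i in range(spec.n_ligands)]
    receptor_ids = [f"R{i:03d}" for i in range(spec.n_receptors)]
    informative = sorted(
        rng.choice(receptor_ids, size=spec.n_informative, replace=False).tolist()
    )
    n = spec.n_ligands
    dg_true = rng.uniform(*spec.dg_range, size=n)
    y = dg_true + rng.normal(scale=spec.noise_sd, size=n)

    descriptors = pd.DataFrame(
        {
            "MW": rng.uniform(200.0, 600.0, n),
            "ALP": rng.uniform(-1.0, 5.0, n),
            "PSA": rng.uniform(20.0, 140.0, n),
            "NHA": rng.integers(1, 11, n),
            "NHD": rng.integers(0, 6, n),
            "NRB": rng.integers(1, 12, n),
            "NAR": rng.integers(0, 5, n),
            "NNH": rng.integers(15, 46, n),
        },
        index=ligand_ids,
    )
    tor = TORSION_PENALTY * descriptors["NRB"].to_numpy(dtype=float)

    term_data: dict[str, np.ndarray] = {}
    score_data: dict[str, np.ndarray] = {}
    for rec in receptor_ids:
        if rec in informative:
            for term, coef in spec.coefficients.items():
                if term == "TOR":
                    continue
                term_data[f"{rec}_{term}"] = (
                    coef * dg_true
                    + _TERM_INTERCEPTS[term]
                    + rng.normal(scale=spec.feature_noise_sd, size=n)
                )
            score_data[rec] = dg_true + rng.normal(scale=spec.score_noise_sd, size=n)
        else:
            for term, (mu, sd) in _DECOY_TERMS.items():
                term_data[f"{rec}_{term}"] = rng.normal(mu, sd, size=n)
            score_data[rec] = rng.normal(-7.5, 1.2, size=n)
        term_data[f"{rec}_TOR"] = tor.copy()

    table = DockingFeatureTable(
        pd.DataFrame(term_data, index=ligand_ids),
        pd.DataFrame(score_data, index=ligand_ids),
        pd.Series(y, index=ligand_ids),
        descriptors,
    )
    # realized R^2 of y against the informative receptors' term features
    x_s = table.feature_matrix(informative).to_numpy()
    design = np.column_stack([np.ones(n), x_s])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    ss_res = float(((y - design @ beta) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    truth = TableGroundTruth(
        informative=informative,
        dg_true=pd.Series(dg_true, index=ligand_ids),
        noise_sd=spec.noise_sd,
        population_r2=1.0 - ss_res / ss_tot,
    )
    return table, truth
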