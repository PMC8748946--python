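"""Receptor structures, ensemble superposition, and docking-box geometry.

Reads receptor conformations from PDB files restricted to a fixed
binding-site residue list, superposes the ensemble onto a chosen reference
by a rigid-body (Kabsch) backbone fit, and derives ligand-position
statistics (centers of geometry, enclosing boxes, principal axes) used to
place an axis-aligned docking box over the orthosteric site.

Conventions: coordinates and cutoffs in angstroms; residue keys are
``(chain id, residue number with insertion code)``; only heavy atoms are
kept; the first model and altloc "A"/blank of a PDB file are read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "BindingSiteDefinition",
    "ReceptorConformation",
    "ReceptorEnsemble",
    "LigandGeometryStats",
    "read_binding_site",
    "read_receptors",
    "superpose_ensemble",
    "kabsch",
    "contact_profile",
    "ligand_geometry_stats",
    "derive_docking_box",
    "write_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

ResidueKey = tuple[str, str]


@dataclass(frozen=True)
class BindingSiteDefinition:
    """Ordered binding-site residue list shared by all downstream indexing.

    ``residues`` holds ``(chain id, residue number, residue name)`` triples;
    the residue name may be ``None`` when the site file does not constrain
    it.  ``contact_cutoff`` is the heavy-atom distance (in angstroms) used
    when profiling ligand contacts.
    """

    residues: tuple[tuple[str, str, str | None], ...]
    contact_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must contain at least one residue")
        keys = [self.key(i) for i in range(len(self.residues))]
        if len(set(keys)) != len(keys):
            raise ValueError("binding-site residue identifiers must be unique")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")

    def key(self, index: int) -> ResidueKey:
        chain, number, _ = self.residues[index]
        return (chain, str(number))

    @property
    def keys(self) -> tuple[ResidueKey, ...]:
        return tuple(self.key(i) for i in range(len(self.residues)))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReceptorConformation:
    """One receptor conformation: heavy-atom coordinates per site residue.

    ``coords`` maps a residue key to an ordered list of
    ``(atom name, xyz)`` pairs (heavy atoms only, sorted by atom name).
    ``backbone`` optionally holds N/CA/C/O coordinates for the whole chain,
    used for ensemble superposition.
    """

    id: str
    coords: dict[ResidueKey, list[tuple[str, np.ndarray]]]
    backbone: dict[ResidueKey, dict[str, np.ndarray]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def atom_names(self, key: ResidueKey) -> list[str]:
        return [name for name, _ in self.coords[key]]

    def residue_coords(self, key: ResidueKey, names: Sequence[str]) -> np.ndarray:
        lookup = dict(self.coords[key])
        return np.array([lookup[n] for n in names], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ReceptorConformation":
        coords = {
            k: [(n, xyz @ rotation.T + translation) for n, xyz in atoms]
            for k, atoms in self.coords.items()
        }
        backbone = {
            k: {n: xyz @ rotation.T + translation for n, xyz in atoms.items()}
            for k, atoms in self.backbone.items()
        }
        return ReceptorConformation(self.id, coords, backbone, dict(self.meta))


@dataclass
class ReceptorEnsemble:
    """An ordered collection of conformations over one binding-site definition."""

    site: BindingSiteDefinition
    members: list[ReceptorConformation]
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("member ids must be unique")
        expected = set(self.site.keys)
        for m in self.members:
            missing = expected - set(m.coords)
            if missing:
                raise ValueError(f"member {m.id} lacks site residues: {sorted(missing)}")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def member(self, member_id: str) -> ReceptorConformation:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def __len__(self) -> int:
        return len(self.members)


def read_binding_site(path: str | Path, contact_cutoff: float = 4.0) -> BindingSiteDefinition:
    """Read a binding-site list from a delimited text file.

    Each non-comment line holds ``chain residue-number [residue-name]``
    separated by whitespace, commas or tabs.
    """
    residues = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) < 2:
            raise ValueError(f"malformed site line: {raw!r}")
        chain, number = parts[0], parts[1]
        name = parts[2].upper() if len(parts) > 2 else None
        residues.append((chain, number, name))
    return BindingSiteDefinition(tuple(residues), contact_cutoff=contact_cutoff)


def _residue_key(chain_id: str, residue) -> ResidueKey:
    _, resseq, icode = residue.id
    return (chain_id, f"{resseq}{icode.strip()}")


def _is_heavy(atom) -> bool:
    element = (atom.element or "").strip().upper()
    if element in ("H", "D"):
        return False
    if not element and atom.get_name().lstrip("0123456789").startswith(("H", "D")):
        return False
    return atom.get_altloc() in (" ", "A")


def read_receptors(paths: Sequence[str | Path], site: BindingSiteDefinition) -> ReceptorEnsemble:
    """Read one conformation per PDB file, restricted to the binding site.

    Raises if any requested site residue is absent from the named chain or
    its residue name conflicts with the site definition (a mutant).
    Hydrogens are dropped; per-residue atom lists are sorted by atom name.
    """
    parser = PDBParser(QUIET=True)
    members = []
    for path in paths:
        path = Path(path)
        structure = parser.get_structure(path.stem, str(path))
        model = next(iter(structure))
        by_key: dict[ResidueKey, object] = {}
        backbone: dict[ResidueKey, dict[str, np.ndarray]] = {}
        for chain in model:
            for residue in chain:
                key = _residue_key(chain.id, residue)
                by_key.setdefault(key, residue)
                bb = {
                    a.get_name(): a.get_coord().astype(float)
                    for a in residue
                    if a.get_name() in BACKBONE_ATOMS and _is_heavy(a)
                }
                if bb:
                    backbone[key] = bb
        coords: dict[ResidueKey, list[tuple[str, np.ndarray]]] = {}
        for chain_id, number, resname in site.residues:
            key = (chain_id, str(number))
            residue = by_key.get(key)
            if residue is None:
                raise ValueError(
                    f"receptor {path.stem}: site residue {number} not found in chain {chain_id}"
                )
            if resname is not None and residue.get_resname().strip().upper() != resname:
                raise ValueError(
                    f"receptor {path.stem}: residue {chain_id}{number} is "
                    f"{residue.get_resname().strip()} but site expects {resname} (mutant?)"
                )
            atoms = sorted(
                ((a.get_name(), a.get_coord().astype(float)) for a in residue if _is_heavy(a)),
                key=lambda pair: pair[0],
            )
            if not atoms:
                raise ValueError(
                    f"receptor {path.stem}: residue {chain_id}{number} has no heavy atoms"
                )
            coords[key] = atoms
        members.append(ReceptorConformation(path.stem, coords, backbone))
    return ReceptorEnsemble(site, members, aligned=False)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (rotation, translation) mapping
    ``mobile`` onto ``target``; proper rotation only (det +1)."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("need >= 3 paired points of identical shape")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ct - rotation @ cm
    return rotation, translation


def _backbone_pairs(member: ReceptorConformation, reference: ReceptorConformation):
    mobile, target = [], []
    for key in sorted(set(member.backbone) & set(reference.backbone)):
        shared = sorted(set(member.backbone[key]) & set(reference.backbone[key]))
        for name in shared:
            mobile.append(member.backbone[key][name])
            target.append(reference.backbone[key][name])
    return np.array(mobile, dtype=float), np.array(target, dtype=float)


def superpose_ensemble(ens: ReceptorEnsemble, reference: str) -> ReceptorEnsemble:
    """Superpose every member's backbone onto the reference member.

    Rigid-body least-squares fit over the N/CA/C/O atoms of all residues
    shared with the reference (whole chain where available).  The reference
    itself is unchanged; the result is marked aligned.
    """
    ref = ens.member(reference)
    aligned_members = []
    for member in ens.members:
        if member.id == reference:
            aligned_members.append(member)
            continue
        mobile, target = _backbone_pairs(member, ref)
        if mobile.shape[0] < 3:
            raise ValueError(
                f"member {member.id}: fewer than 3 shared backbone atoms with {reference}"
            )
        rotation, translation = kabsch(mobile, target)
        aligned_members.append(member.transformed(rotation, translation))
    return ReceptorEnsemble(ens.site, aligned_members, aligned=True)


def backbone_rmsd(a: ReceptorConformation, b: ReceptorConformation) -> float:
    """Backbone RMSD over shared N/CA/C/O atoms, no fitting."""
    pa, pb = _backbone_pairs(a, b)
    if pa.shape[0] == 0:
        raise ValueError("no shared backbone atoms")
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def contact_profile(
    ens: ReceptorEnsemble,
    ligands: Mapping[str, np.ndarray],
    cutoff: float | None = None,
) -> dict[ResidueKey, float]:
    """Fraction of members in which each site residue contacts its ligand.

    A residue is in contact when any of its heavy atoms lies within
    ``cutoff`` of any ligand heavy atom of the same complex.  Members with
    an empty ligand set are excluded with a warning.  Contacts are
    intra-complex, so no alignment is required.
    """
    cutoff = ens.site.contact_cutoff if cutoff is None else cutoff
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    counted = 0
    hits = {key: 0 for key in ens.site.keys}
    for member in ens.members:
        lig = np.asarray(ligands.get(member.id, np.empty((0, 3))), dtype=float)
        if lig.size == 0:
            warnings.warn(f"member {member.id}: empty ligand set, excluded from contact profile")
            continue
        counted += 1
        for key in ens.site.keys:
            res = np.array([xyz for _, xyz in member.coords[key]], dtype=float)
            d2 = ((res[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= cutoff**2:
                hits[key] += 1
    if counted == 0:
        raise ValueError("no member has a non-empty ligand set")
    return {key: hits[key] / counted for key in ens.site.keys}


@dataclass
class LigandGeometryStats:
    """Per-ligand centers of geometry and enclosing boxes, plus the
    principal axes of the set of centers (variances non-increasing)."""

    ids: list[str]
    centers: np.ndarray  # (n, 3)
    box_min: np.ndarray  # (n, 3)
    box_max: np.ndarray  # (n, 3)
    principal_axes: np.ndarray  # (3, 3), rows are axes
    variances: np.ndarray  # (3,)

    def center(self, ligand_id: str) -> np.ndarray:
        return self.centers[self.ids.index(ligand_id)]

    def box(self, ligand_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.ids.index(ligand_id)
        return self.box_min[i], self.box_max[i]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ids": self.ids,
            "centers": self.centers.tolist(),
            "box_min": self.box_min.tolist(),
            "box_max": self.box_max.tolist(),
            "principal_axes": self.principal_axes.tolist(),
            "variances": self.variances.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def ligand_geometry_stats(ligands: Mapping[str, np.ndarray]) -> LigandGeometryStats:
    """Centers of geometry, enclosing boxes, and PCA of the centers.

    The principal axes are the eigenvectors of the covariance of the
    ligand centers, ordered by decreasing variance.  A single ligand
    yields zero variances and (arbitrary) orthonormal axes.
    """
    if not ligands:
        raise ValueError("at least one ligand required")
    ids = sorted(ligands)
    coords = [np.atleast_2d(np.asarray(ligands[i], dtype=float)) for i in ids]
    for lig_id, xyz in zip(ids, coords):
        if xyz.size == 0:
            raise ValueError(f"ligand {lig_id} has no atoms")
    centers = np.array([xyz.mean(axis=0) for xyz in coords])
    box_min = np.array([xyz.min(axis=0) for xyz in coords])
    box_max = np.array([xyz.max(axis=0) for xyz in coords])
    if len(ids) < 2:
        axes, variances = np.eye(3), np.zeros(3)
    else:
        cov = np.cov(centers, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        variances = np.clip(eigvals[order], 0.0, None)
        axes = eigvecs[:, order].T
    return LigandGeometryStats(ids, centers, box_min, box_max, axes, variances)


def derive_docking_box(
    stats: LigandGeometryStats,
    include: Iterable[str],
    exclude: Iterable[str] = (),
    padding: float | Sequence[float] = 0.0,
) -> dict:
    """Axis-aligned docking box from the union of included ligand boxes.

    The union box is expanded by ``padding`` on every face (scalar or
    per-axis); the report lists the overlap volume with each excluded
    ligand's enclosing box, so an allosteric pocket can be checked to lie
    outside the box.
    """
    include = list(include)
    if not include:
        raise ValueError("include set must be non-empty")
    pad = np.broadcast_to(np.asarray(padding, dtype=float), (3,))
    lows = np.array([stats.box(i)[0] for i in include])
    highs = np.array([stats.box(i)[1] for i in include])
    lo = lows.min(axis=0) - pad
    hi = highs.max(axis=0) + pad
    overlaps = {}
    for lig_id in exclude:
        elo, ehi = stats.box(lig_id)
        extent = np.clip(np.minimum(hi, ehi) - np.maximum(lo, elo), 0.0, None)
        overlaps[lig_id] = float(np.prod(extent))
    return {
        "center": (lo + hi) / 2.0,
        "sizes": hi - lo,
        "min": lo,
        "max": hi,
        "excluded_overlap_volume": overlaps,
    }


def write_pdb(member: ReceptorConformation, site: BindingSiteDefinition, path: str | Path) -> None:
    """Write the site residues of one conformation as plain ATOM records."""
    lines = []
    serial = 1
    for chain, number, resname in site.residues:
        key = (chain, str(number))
        name = (resname or "UNK")[:3]
        for atom, xyz in member.coords[key]:
            atom_field = atom if len(atom) == 4 else f" {atom:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {atom_field[:4]} {name:>3s} {chain[:1]}{int_or_str(number):>4s}"
                f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def int_or_str(number: str) -> str:
    digits = "".join(ch for ch in str(number) if ch.isdigit() or ch == "-")
    return digits or str(number)
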