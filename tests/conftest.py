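"""Shared fixtures: toy PDB builders, DLG text, small synthetic tables."""

from __future__ import annotations

import numpy as np
import pytest

from docksel import (
    BindingSiteDefinition,
    ReceptorConformation,
    ReceptorEnsemble,
    TableSpec,
    gen_table,
)


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, element=None, altloc=" "):
    element = element or name.lstrip("0123456789")[0]
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}"
    )


def write_toy_pdb(path, residues, chain="A"):
    """residues: list of (resseq, resname, [(atom_name, xyz), ...])."""
    lines = []
    serial = 1
    for resseq, resname, atoms in residues:
        for name, xyz in atoms:
            lines.append(pdb_atom_line(serial, name, resname, chain, resseq, xyz))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def standard_residue(resseq, resname="ALA", origin=(0.0, 0.0, 0.0), extra=()):
    """Backbone (N, CA, C, O) plus optional extra atoms around an origin."""
    o = np.asarray(origin, dtype=float)
    atoms = [
        ("N", o + [0.0, 0.0, 0.0]),
        ("CA", o + [1.5, 0.0, 0.0]),
        ("C", o + [2.2, 1.3, 0.0]),
        ("O", o + [1.8, 2.4, 0.2]),
    ]
    atoms += [(name, o + np.asarray(off, dtype=float)) for name, off in extra]
    return (resseq, resname, atoms)


def make_conformation(member_id, site_keys, coords_array, atom_names):
    """Build a ReceptorConformation from an (K, A, 3) coordinate array."""
    coords = {
        key: [(atom_names[a], coords_array[k, a].copy()) for a in range(len(atom_names))]
        for k, key in enumerate(site_keys)
    }
    return ReceptorConformation(member_id, coords)


def random_ensemble(rng, n_members, n_residues, atoms_per_residue=3):
    """An already-aligned ensemble with fully random coordinates."""
    site = BindingSiteDefinition(
        tuple(("A", str(k + 1), None) for k in range(n_residues))
    )
    atom_names = [f"C{a+1}" for a in range(atoms_per_residue)]
    members = [
        make_conformation(
            f"M{i:02d}",
            site.keys,
            rng.normal(scale=4.0, size=(n_residues, atoms_per_residue, 3)),
            atom_names,
        )
        for i in range(n_members)
    ]
    return ReceptorEnsemble(site, members, aligned=True)


DLG_HEADER = "AutoDock 4.2 Release\n\n"


def dlg_run_block(run, total, vhd, elc, internal, tor):
    intermol = vhd + elc
    return "\n".join(
        [
            f"DOCKED: USER    Run = {run}",
            "DOCKED: USER",
            f"DOCKED: USER    Estimated Free Energy of Binding    =  {total:+7.2f} kcal/mol",
            f"DOCKED: USER    (1) Final Intermolecular Energy     =  {intermol:+7.2f} kcal/mol",
            f"DOCKED: USER        vdW + Hbond + desolv Energy     =  {vhd:+7.2f} kcal/mol",
            f"DOCKED: USER        Electrostatic Energy            =  {elc:+7.2f} kcal/mol",
            f"DOCKED: USER    (2) Final Total Internal Energy     =  {internal:+7.2f} kcal/mol",
            f"DOCKED: USER    (3) Torsional Free Energy           =  {tor:+7.2f} kcal/mol",
            "DOCKED: ENDMDL",
        ]
    )


def dlg_text(runs):
    """runs: list of dicts with total/vhd/elc/internal/tor."""
    blocks = [
        dlg_run_block(i + 1, r["total"], r["vhd"], r["elc"], r["internal"], r["tor"])
        for i, r in enumerate(runs)
    ]
    return DLG_HEADER + "\n\n".join(blocks) + "\n"


@pytest.fixture(scope="session")
def small_table():
    """A compact planted-signal table reused by cheap tests."""
    table, truth = gen_table(TableSpec(n_ligands=40, n_receptors=6, seed=7))
    return table, truth
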