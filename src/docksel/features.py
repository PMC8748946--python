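"""Docking feature tables: AutoDock4 energetics, descriptors, affinities.

The ligand x receptor grid of best-pose docking energetics is the input to
both the docking-without-learning scenarios and the random-forest
rescoring.  Four terms are kept per complex — VHD (intermolecular van der
Waals + H-bond + desolvation), ELC (intermolecular electrostatics), TOR
(torsional entropy penalty) and INT (ligand internal energy in the bound
state) — plus the total docking score of the best pose.  Eight simple
molecular descriptors per ligand (MW, ALP, PSA, NHA, NHD, NRB, NAR, NNH)
and the experimental binding free energy complete the table, giving
4R receptor-dependent features and 4R + 8 in total.

The energy terms are consumed as parsed docking output; no force-field
evaluation happens here.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TERMS",
    "GAS_CONSTANT_KCAL",
    "DockingTerms",
    "MolecularDescriptors",
    "AffinityRecord",
    "DockingFeatureTable",
    "parse_dlg",
    "ki_to_dg",
    "build_table",
    "read_table",
    "write_table",
    "read_affinities",
]

logger = logging.getLogger(__name__)

TERMS = ("VHD", "ELC", "TOR", "INT")
DESCRIPTOR_NAMES = ("MW", "ALP", "PSA", "NHA", "NHD", "NRB", "NAR", "NNH")
TARGET_COLUMN = "dG_exp"

#: Gas constant in kcal/(mol K), used for Ki -> free-energy conversion.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class DockingTerms:
    """Best-pose energetics of one ligand-receptor complex (kcal/mol)."""

    VHD: float
    ELC: float
    TOR: float
    INT: float
    total_score: float

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"{f.name} must be finite, got {value}")
        if self.TOR < 0:
            warnings.warn(
                f"TOR = {self.TOR} < 0: the torsional term is a non-negative "
                "penalty under the AutoDock convention"
            )


@dataclass(frozen=True)
class MolecularDescriptors:
    """Eight simple receptor-independent ligand descriptors."""

    MW: float
    ALP: float
    PSA: float
    NHA: int
    NHD: int
    NRB: int
    NAR: int
    NNH: int

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ValueError("MW must be positive")
        for name in ("NHA", "NHD", "NRB", "NAR", "NNH"):
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value}")


@dataclass(frozen=True)
class AffinityRecord:
    """Experimental inhibition constant and its free-energy equivalent."""

    ligand_id: str
    ki: float  # molar
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.ki <= 0:
            raise ValueError("Ki must be positive")

    @property
    def dg(self) -> float:
        return ki_to_dg(self.ki, self.temperature)


def ki_to_dg(ki: float, temperature: float = 298.15) -> float:
    """Binding free energy from an inhibition constant: dG = R T ln Ki.

    Ki in molar, temperature in kelvin, result in kcal/mol (negative for
    sub-molar Ki).
    """
    if ki <= 0:
        raise ValueError("Ki must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(ki)


# --- AutoDock4 DLG parsing -------------------------------------------------

_DLG_FIELDS = {
    "total_score": re.compile(r"Estimated Free Energy of Binding\s*=\s*([-+]?\d+\.?\d*)"),
    "vhd": re.compile(r"vdW \+ Hbond \+ desolv Energy\s*=\s*([-+]?\d+\.?\d*)"),
    "elc": re.compile(r"Electrostatic Energy\s*=\s*([-+]?\d+\.?\d*)"),
    "int": re.compile(r"Final Total Internal Energy\s*=\s*([-+]?\d+\.?\d*)"),
    "tor": re.compile(r"Torsional Free Energy\s*=\s*([-+]?\d+\.?\d*)"),
}
_RUN_RE = re.compile(r"^DOCKED:\s*USER\s*Run\s*=\s*(\d+)")


def parse_dlg(path: str | Path) -> DockingTerms:
    """Extract best-pose energetics from an AutoDock4 DLG log.

    All ``DOCKED: USER`` run blocks are scanned and the run with the lowest
    estimated free energy of binding is returned (the top-ranked cluster's
    lowest-energy member, since cluster rank follows lowest energy).

    Line-to-term mapping: VHD <- "vdW + Hbond + desolv Energy",
    ELC <- "Electrostatic Energy", TOR <- "Torsional Free Energy",
    INT <- "Final Total Internal Energy",
    total <- "Estimated Free Energy of Binding".
    """
    text = Path(path).read_text()
    runs: list[dict[str, float]] = []
    current: dict[str, float] | None = None
    for line in text.splitlines():
        if not line.startswith("DOCKED:"):
            continue
        if _RUN_RE.match(line):
            current = {}
            runs.append(current)
            continue
        if current is None:
            continue
        for key, pattern in _DLG_FIELDS.items():
            m = pattern.search(line)
            if m:
                current[key] = float(m.group(1))
    complete = [r for r in runs if len(r) == len(_DLG_FIELDS)]
    if not complete:
        raise ValueError(
            f"{path}: no complete docked-results section (DOCKED: USER Run blocks) found"
        )
    best = min(complete, key=lambda r: r["total_score"])
    return DockingTerms(
        VHD=best["vhd"],
        ELC=best["elc"],
        TOR=best["tor"],
        INT=best["int"],
        total_score=best["total_score"],
    )


# --- feature table ---------------------------------------------------------


class DockingFeatureTable:
    """Complete ligand x receptor grid of docking terms plus per-ligand data.

    ``terms`` is an L x 4R frame with columns ``<receptor>_<TERM>``;
    ``scores`` the L x R per-receptor total docking scores; ``descriptors``
    an optional L x 8 frame; ``y`` the experimental binding free energies.
    """

    def __init__(
        self,
        terms: pd.DataFrame,
        scores: pd.DataFrame,
        y: pd.Series,
        descriptors: pd.DataFrame | None = None,
    ) -> None:
        self.receptor_ids = list(scores.columns)
        self.ligand_ids = list(scores.index)
        if len(set(self.receptor_ids)) != len(self.receptor_ids):
            raise ValueError("duplicate receptor ids")
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("duplicate ligand ids")
        expected = [f"{r}_{t}" for r in self.receptor_ids for t in TERMS]
        if sorted(terms.columns) != sorted(expected):
            raise ValueError("terms frame must have exactly the 4R <receptor>_<TERM> columns")
        if list(terms.index) != self.ligand_ids or list(y.index) != self.ligand_ids:
            raise ValueError("terms/scores/y must share one ligand index")
        if terms.isna().any().any() or scores.isna().any().any() or y.isna().any():
            raise ValueError("missing cells are not allowed in the feature grid")
        if descriptors is not None:
            if list(descriptors.columns) != list(DESCRIPTOR_NAMES):
                raise ValueError(f"descriptor columns must be {DESCRIPTOR_NAMES}")
            if list(descriptors.index) != self.ligand_ids:
                raise ValueError("descriptors must share the ligand index")
        self.terms = terms[expected].astype(float)
        self.scores = scores.astype(float)
        self.y = y.astype(float)
        self.descriptors = None if descriptors is None else descriptors.astype(float)

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_ids)

    def feature_matrix(
        self,
        receptors: list[str] | None = None,
        include_descriptors: bool = False,
    ) -> pd.DataFrame:
        """4k (+8) feature columns for the chosen receptor subset."""
        receptors = self.receptor_ids if receptors is None else list(receptors)
        unknown = set(receptors) - set(self.receptor_ids)
        if unknown:
            raise KeyError(f"unknown receptors: {sorted(unknown)}")
        cols = [f"{r}_{t}" for r in receptors for t in TERMS]
        x = self.terms[cols]
        if include_descriptors:
            if self.descriptors is None:
                raise ValueError("table has no molecular descriptors")
            x = pd.concat([x, self.descriptors], axis=1)
        return x

    def subset_receptors(self, receptors: list[str]) -> "DockingFeatureTable":
        cols = [f"{r}_{t}" for r in receptors for t in TERMS]
        return DockingFeatureTable(
            self.terms[cols], self.scores[receptors], self.y, self.descriptors
        )


def build_table(
    terms: Mapping[tuple[str, str], DockingTerms],
    affinities: Mapping[str, float],
    descriptors: Mapping[str, MolecularDescriptors] | None = None,
) -> DockingFeatureTable:
    """Assemble the feature table from per-complex terms and per-ligand data.

    ``terms`` maps ``(ligand id, receptor id)`` to :class:`DockingTerms`
    and must cover the complete grid; ``affinities`` maps ligand id to the
    experimental binding free energy in kcal/mol.
    """
    ligand_ids = sorted({lig for lig, _ in terms})
    receptor_ids = sorted({rec for _, rec in terms})
    missing = [
        (lig, rec) for lig in ligand_ids for rec in receptor_ids if (lig, rec) not in terms
    ]
    if missing:
        raise ValueError(f"incomplete grid; missing cells: {missing[:5]}...")
    if set(affinities) != set(ligand_ids):
        raise ValueError("affinities must cover exactly the ligand set")
    term_data = {
        f"{rec}_{t}": [getattr(terms[(lig, rec)], t) for lig in ligand_ids]
        for rec in receptor_ids
        for t in TERMS
    }
    score_data = {
        rec: [terms[(lig, rec)].total_score for lig in ligand_ids] for rec in receptor_ids
    }
    desc_frame = None
    if descriptors is not None:
        if set(descriptors) != set(ligand_ids):
            raise ValueError("descriptors must cover exactly the ligand set")
        desc_frame = pd.DataFrame(
            {
                name: [getattr(descriptors[lig], name) for lig in ligand_ids]
                for name in DESCRIPTOR_NAMES
            },
            index=ligand_ids,
        )
    return DockingFeatureTable(
        pd.DataFrame(term_data, index=ligand_ids),
        pd.DataFrame(score_data, index=ligand_ids),
        pd.Series({lig: affinities[lig] for lig in ligand_ids})[ligand_ids],
        desc_frame,
    )


def write_table(table: DockingFeatureTable, path: str | Path) -> None:
    """Write the table as one CSV: terms, scores, descriptors, dG_exp."""
    frame = table.terms.copy()
    for rec in table.receptor_ids:
        frame[f"{rec}_SCORE"] = table.scores[rec]
    if table.descriptors is not None:
        frame = pd.concat([frame, table.descriptors], axis=1)
    frame[TARGET_COLUMN] = table.y
    frame.index.name = "ligand"
    frame.to_csv(path)


def read_table(path: str | Path) -> DockingFeatureTable:
    """Read a table written by :func:`write_table` (lossless round-trip)."""
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise ValueError(f"{path}: empty feature table")
    frame.index = frame.index.astype(str)
    term_cols, score_cols, desc_cols, unknown = [], [], [], []
    receptor_ids = set()
    for col in frame.columns:
        if col == TARGET_COLUMN:
            continue
        if col in DESCRIPTOR_NAMES:
            desc_cols.append(col)
            continue
        stem, _, suffix = col.rpartition("_")
        if stem and suffix in TERMS:
            term_cols.append(col)
            receptor_ids.add(stem)
        elif stem and suffix == "SCORE":
            score_cols.append(col)
        else:
            unknown.append(col)
    if unknown:
        raise ValueError(f"{path}: unrecognised columns: {unknown}")
    if TARGET_COLUMN not in frame.columns:
        raise ValueError(f"{path}: missing target column {TARGET_COLUMN!r}")
    receptors = sorted(receptor_ids)
    scores = pd.DataFrame(
        {rec: frame[f"{rec}_SCORE"] for rec in receptors if f"{rec}_SCORE" in frame}
    )
    if list(scores.columns) != receptors:
        missing = sorted(set(receptors) - set(scores.columns))
        raise ValueError(f"{path}: missing SCORE columns for receptors {missing}")
    descriptors = None
    if desc_cols:
        if sorted(desc_cols) != sorted(DESCRIPTOR_NAMES):
            raise ValueError(f"{path}: incomplete descriptor block: {sorted(desc_cols)}")
        descriptors = frame[list(DESCRIPTOR_NAMES)]
    return DockingFeatureTable(frame[term_cols], scores, frame[TARGET_COLUMN], descriptors)


def read_affinities(path: str | Path, temperature: float = 298.15) -> dict[str, float]:
    """Read per-ligand affinities from CSV into dG (kcal/mol).

    Expected columns: ``ligand`` plus either ``dG`` (used as-is) or
    ``Ki_nM``/``Ki_M`` (converted via dG = R T ln Ki).  An optional
    ``relation`` column filters records: only '=' rows are kept, rejected
    rows are counted in the log.
    """
    frame = pd.read_csv(path)
    if "ligand" not in frame.columns:
        raise ValueError(f"{path}: missing 'ligand' column")
    if "relation" in frame.columns:
        keep = frame["relation"].astype(str).str.strip() == "="
        rejected = int((~keep).sum())
        if rejected:
            logger.info("%s: rejected %d non-equality affinity records", path, rejected)
        frame = frame[keep]
    out: dict[str, float] = {}
    for _, row in frame.iterrows():
        lig = str(row["ligand"])
        if "dG" in frame.columns and np.isfinite(row.get("dG", np.nan)):
            out[lig] = float(row["dG"])
        elif "Ki_nM" in frame.columns:
            out[lig] = ki_to_dg(float(row["Ki_nM"]) * 1e-9, temperature)
        elif "Ki_M" in frame.columns:
            out[lig] = ki_to_dg(float(row["Ki_M"]), temperature)
        else:
            raise ValueError(f"{path}: need a 'dG', 'Ki_nM' or 'Ki_M' column")
    return out
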