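"""Domain types and file I/O for structures, sequences and score tables.

A :class:`ProteinModel` is an ordered list of residues with atom
coordinates; it is the common currency of the feature and metric layers.
Parsing is deliberately strict: every residue must carry a CA atom and the
residue numbering must increase, so downstream per-residue feature vectors
always have length ``L`` equal to the sequence length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

# The nine externally computed potential / QA scores consumed as features.
EXTERNAL_SCORE_NAMES = (
    "dfire2",
    "rwplus",
    "rf_cb_srs_od",
    "dope",
    "goap",
    "opus",
    "proq2",
    "modelevaluator",
    "qprob",
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class StructureError(ValueError):
    """Raised when a structure file violates the single-chain CA-complete contract."""


@dataclass
class Residue:
    """One amino-acid residue with its atom coordinates (Å).

    ``index`` is the 1-based sequence position; ``atoms`` maps PDB atom
    names (``"CA"``, ``"N"``, ``"C"``, ...) to 3-vectors.
    """

    index: int
    aa: str
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aa not in AA_ALPHABET and self.aa != "X":
            raise StructureError(f"residue {self.index}: unknown amino acid {self.aa!r}")
        if "CA" not in self.atoms:
            raise StructureError(f"residue {self.index} ({self.aa}): missing CA atom")
        for name, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise StructureError(f"residue {self.index}: bad coordinate for atom {name}")
            self.atoms[name] = arr

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class ProteinModel:
    """A single-chain protein model: ordered residues plus derived sequence."""

    model_id: str
    residues: List[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError(f"model {self.model_id}: no residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError(f"model {self.model_id}: residue indices not strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of CA coordinates."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinModel":
        """Return a rigid-body transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        residues = [
            Residue(
                index=r.index,
                aa=r.aa,
                atoms={n: rotation @ xyz + translation for n, xyz in r.atoms.items()},
            )
            for r in self.residues
        ]
        return ProteinModel(model_id=self.model_id, residues=residues)


@dataclass
class PredictionInputs:
    """Sequence-based predictions: 3-state secondary structure and 2-state accessibility.

    ``ss_pred`` uses {H, E, C}; ``sa_pred`` uses {e, b} (exposed/buried).
    These emulate what SpineX- and SSpro-style predictors supply for a target.
    """

    ss_pred: Optional[str] = None
    sa_pred: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ss_pred is not None and set(self.ss_pred) - set("HEC"):
            raise ValueError("ss_pred must be over {H,E,C}")
        if self.sa_pred is not None and set(self.sa_pred) - set("eb"):
            raise ValueError("sa_pred must be over {e,b}")


@dataclass
class ExternalScores:
    """Raw per-model scores from external potentials/QA tools; any may be absent."""

    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if name not in EXTERNAL_SCORE_NAMES:
                raise ValueError(f"unknown external score {name!r}")
            if not math.isfinite(v):
                raise ValueError(f"external score {name} not finite: {v}")

    def get(self, name: str) -> Optional[float]:
        return self.values.get(name)


@dataclass
class ModelPool:
    """All candidate models for one target, with optional native and external scores."""

    target_id: str
    models: List[ProteinModel]
    native: Optional[ProteinModel] = None
    external: Dict[str, ExternalScores] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError(f"pool {self.target_id}: duplicate model ids")
        if self.native is not None and self.models:
            if self.native.sequence != self.models[0].sequence:
                raise ValueError(f"pool {self.target_id}: native sequence mismatch")


_PARSER = PDBParser(QUIET=True)


def read_pdb(path, model_id: Optional[str] = None) -> ProteinModel:
    """Read the first chain of the first MODEL block of a PDB file.

    Altloc conflicts resolve to the highest-occupancy conformer (Biopython's
    disordered-atom selection). Hetero residues and waters are skipped; a
    standard residue without a CA atom is an error.
    """
    path = Path(path)
    if model_id is None:
        model_id = path.stem
    try:
        structure = _PARSER.get_structure(model_id, str(path))
    except ValueError as e:
        raise StructureError(f"{path}: {e}") from e
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no ATOM records")
    chains = list(models[0])
    if not chains:
        raise StructureError(f"{path}: no chains")
    residues: List[Residue] = []
    for res in chains[0]:
        if res.id[0] != " ":  # skip HETATM / water
            continue
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        atoms = {atom.get_name(): np.array(atom.get_coord(), dtype=float) for atom in res}
        if "CA" not in atoms:
            raise StructureError(
                f"{path}: residue {res.get_resname()} {res.id[1]} has no CA atom"
            )
        residues.append(Residue(index=len(residues) + 1, aa=aa, atoms=atoms))
    if not residues:
        raise StructureError(f"{path}: no standard residues in first chain")
    return ProteinModel(model_id=model_id, residues=residues)


_AA1TO3 = {v: k for k, v in protein_letters_3to1.items()}
_AA1TO3["X"] = "UNK"

# Canonical backbone-first atom order for output records.
_ATOM_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}


def write_pdb(model: ProteinModel, path) -> None:
    """Write a ProteinModel as standard ATOM records (8.3 coordinate fields)."""
    lines = []
    serial = 1
    for res in model.residues:
        res3 = _AA1TO3.get(res.aa, "UNK")
        for name in sorted(res.atoms, key=lambda n: (_ATOM_ORDER.get(n, 99), n)):
            x, y, z = res.atoms[name]
            element = name.strip()[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{res3:>4s} A{res.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> str:
    """Read a single-record FASTA and return the uppercase sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly 1 FASTA record, found {len(records)}")
    return str(records[0].seq).upper().replace(" ", "")


def read_score_table(path) -> Dict[str, ExternalScores]:
    """Read a TSV of raw external scores keyed by model id.

    Header must contain a ``model`` column; other columns are matched
    case-insensitively against the known score names. Empty cells are
    recorded as missing (imputation happens at feature assembly, not here).
    """
    df = pd.read_csv(path, sep="\t", dtype={"model": str})
    if "model" not in df.columns:
        raise ValueError(f"{path}: missing 'model' column")
    if df["model"].duplicated().any():
        dups = df["model"][df["model"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate model ids {dups}")
    score_cols = {}
    for col in df.columns:
        if col == "model":
            continue
        key = col.strip().lower()
        if key in EXTERNAL_SCORE_NAMES:
            score_cols[col] = key
    out: Dict[str, ExternalScores] = {}
    for _, row in df.iterrows():
        values = {}
        for col, key in score_cols.items():
            cell = row[col]
            if pd.isna(cell):
                continue
            v = float(cell)  # raises on non-numeric
            values[key] = v
        out[row["model"]] = ExternalScores(values=values)
    return out


def read_prediction_string(path, length: Optional[int] = None) -> str:
    """Read a one-line plain-text prediction string (SS or SA)."""
    text = Path(path).read_text().strip()
    if "\n" in text:
        raise ValueError(f"{path}: expected a single line")
    if length is not None and len(text) != length:
        raise ValueError(f"{path}: prediction length {len(text)} != expected {length}")
    return text
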