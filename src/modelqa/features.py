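"""Feature extraction and assembly for single-model quality assessment.

Sixteen features describe a model: seven physio-chemical scores computed
from the structure (surface, exposed mass, exposed surface, solvent
accessibility agreement, secondary-structure similarity, secondary-structure
penalty, Euclidean compactness) and nine scores consumed from external
potentials/QA tools. Three of the external energies (DFIRE2, RWplus,
RF_CB_SRS_OD) are normalized by fixed length-dependent linear maps; the
remainder are mapped or passed through to [0, 1]. Any feature that cannot
be computed is imputed at the neutral value 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from modelqa.geometry import SasaResult, assign_secondary_structure, distance_matrix, shrake_rupley_sasa
from modelqa.structure_model import ExternalScores, PredictionInputs, ProteinModel

# Canonical feature order (structural block, energy/QA block, SS block, compactness, Qprob).
FEATURE_KEYS_16: Tuple[str, ...] = (
    "SU", "EM", "ES", "SA",
    "RF_CB_SRS_OD", "DFIRE2", "DOPE", "GOAP", "OPUS", "PROQ2",
    "RWPLUS", "MODELEVALUATOR",
    "SS", "SP", "EC", "QPROB",
)

# The reduced 9-feature set used by the final predictor.
FEATURE_KEYS_9: Tuple[str, ...] = (
    "SU", "DOPE", "GOAP", "OPUS", "RWPLUS", "MODELEVALUATOR", "SP", "EC", "QPROB",
)

IMPUTED_VALUE = 0.5

# Hydrophobic/nonpolar residues for the surface score.
NONPOLAR_RESIDUES = frozenset("AVLIPFMWGC")

# Average residue masses (Da; residue masses, i.e. amino acid minus water).
RESIDUE_MASS: Dict[str, float] = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
    "X": 110.0,
}

MAX_CA_CA_SPAN = 3.8  # Å, maximum consecutive-CA distance in an extended chain

# Linear normalization constants for raw energies: score = -P / (c * L), clamped.
ENERGY_NORM_DFIRE2 = 1.971
ENERGY_NORM_RWPLUS = 232.6
# RF_CB_SRS_OD uses (700 - P) / (1000 + 0.4823 L).
RF_OFFSET = 700.0
RF_BASE = 1000.0
RF_SLOPE = 0.4823
# Calibration constants for energies whose published normalization is unspecified.
ENERGY_NORM_DOPE = 2.0
ENERGY_NORM_GOAP = 20.0
ENERGY_NORM_OPUS = 2.0


@dataclass(frozen=True)
class FeatureSetConfig:
    """Named, ordered feature subset: ``full16`` or ``deepqa9``."""

    name: str
    keys: Tuple[str, ...]

    @classmethod
    def from_name(cls, name: str) -> "FeatureSetConfig":
        if name == "full16":
            return cls(name="full16", keys=FEATURE_KEYS_16)
        if name == "deepqa9":
            return cls(name="deepqa9", keys=FEATURE_KEYS_9)
        raise ValueError(f"unknown feature set {name!r}; expected 'full16' or 'deepqa9'")

    @property
    def n_features(self) -> int:
        return len(self.keys)


FULL16 = FeatureSetConfig.from_name("full16")
DEEPQA9 = FeatureSetConfig.from_name("deepqa9")


@dataclass
class FeatureVector:
    """Ordered named feature values in [0, 1] with per-entry provenance.

    Provenance is ``computed`` (from the structure), ``external`` (from a
    score table, normalized here) or ``imputed`` (missing input, neutral 0.5).
    """

    model_id: str
    config: FeatureSetConfig
    values: Dict[str, float]
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.config.keys) - set(self.values)
        if missing:
            raise ValueError(f"feature vector missing keys {sorted(missing)}")
        for k in self.config.keys:
            v = self.values[k]
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"feature {k} = {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in self.config.keys], dtype=float)

    @property
    def n_imputed(self) -> int:
        return sum(1 for k in self.config.keys if self.provenance.get(k) == "imputed")


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def normalize_energy_scores(raw: ExternalScores, L: int) -> Dict[str, float]:
    """Normalize DFIRE2, RWplus and RF_CB_SRS_OD raw energies to [0, 1].

    DFIRE2 and RWplus map as ``-P / (c L)`` with c = 1.971 and 232.6
    respectively; RF_CB_SRS_OD maps as ``(700 - P) / (1000 + 0.4823 L)``.
    Results below zero clamp to 0, above one to 1. Absent scores are left
    absent (imputed later, at assembly).
    """
    if L <= 0:
        raise ValueError(f"sequence length must be positive, got {L}")
    out: Dict[str, float] = {}
    p = raw.get("dfire2")
    if p is not None:
        out["DFIRE2"] = _clamp01(-p / (ENERGY_NORM_DFIRE2 * L))
    p = raw.get("rwplus")
    if p is not None:
        out["RWPLUS"] = _clamp01(-p / (ENERGY_NORM_RWPLUS * L))
    p = raw.get("rf_cb_srs_od")
    if p is not None:
        out["RF_CB_SRS_OD"] = _clamp01((RF_OFFSET - p) / (RF_BASE + RF_SLOPE * L))
    return out


def normalize_auxiliary_energy_scores(raw: ExternalScores, L: int) -> Dict[str, float]:
    """Map the remaining external scores to [0, 1].

    Dope, GOAP and OPUS raw energies use the same ``-P / (c L)`` form with
    calibration constants (2.0, 20.0, 2.0); ProQ2, ModelEvaluator and Qprob
    already live in [0, 1] and are clamped pass-through.
    """
    if L <= 0:
        raise ValueError(f"sequence length must be positive, got {L}")
    out: Dict[str, float] = {}
    for name, key, c in (
        ("dope", "DOPE", ENERGY_NORM_DOPE),
        ("goap", "GOAP", ENERGY_NORM_GOAP),
        ("opus", "OPUS", ENERGY_NORM_OPUS),
    ):
        p = raw.get(name)
        if p is not None:
            out[key] = _clamp01(-p / (c * L))
    for name, key in (("proq2", "PROQ2"), ("modelevaluator", "MODELEVALUATOR"), ("qprob", "QPROB")):
        p = raw.get(name)
        if p is not None:
            out[key] = _clamp01(p)
    return out


def surface_score(sasa: SasaResult, model: ProteinModel) -> float:
    """SU: exposed-nonpolar surface area over total surface area."""
    total = float(sasa.absolute.sum())
    if total <= 0.0:
        return 0.0
    mask = np.array(
        [aa in NONPOLAR_RESIDUES for aa in model.sequence], dtype=bool
    ) & sasa.exposed
    return _clamp01(float(sasa.absolute[mask].sum()) / total)


def exposed_mass_score(sasa: SasaResult, model: ProteinModel) -> float:
    """EM: fraction of residue mass belonging to exposed residues."""
    masses = np.array([RESIDUE_MASS.get(aa, RESIDUE_MASS["X"]) for aa in model.sequence])
    total = float(masses.sum())
    if total <= 0.0:
        return 0.0
    return _clamp01(float(masses[sasa.exposed].sum()) / total)


def exposed_surface_score(sasa: SasaResult, model: ProteinModel) -> float:
    """ES: total accessible area over the summed per-residue reference maxima."""
    from modelqa.geometry import MAX_ASA

    ref = sum(MAX_ASA.get(aa, MAX_ASA["X"]) for aa in model.sequence)
    if ref <= 0.0:
        return 0.0
    return _clamp01(float(sasa.absolute.sum()) / ref)


def sa_agreement_score(sasa: SasaResult, sa_pred: str) -> float:
    """SA: fraction of residues whose 2-state exposure matches the prediction."""
    if len(sa_pred) != len(sasa.exposed):
        raise ValueError(f"sa_pred length {len(sa_pred)} != model length {len(sasa.exposed)}")
    model_labels = np.where(sasa.exposed, "e", "b")
    pred = np.array(list(sa_pred))
    return float((model_labels == pred).mean())


def ss_similarity_score(ss_model: str, ss_pred: str) -> float:
    """SS: Q3 fraction of identical 3-state labels between model and prediction."""
    if len(ss_model) != len(ss_pred):
        raise ValueError(f"SS string lengths differ: {len(ss_model)} vs {len(ss_pred)}")
    return float(np.mean([a == b for a, b in zip(ss_model, ss_pred)]))


def ss_penalty_score(ss_model: str, ss_pred: str) -> float:
    """SP: agreement restricted to positions predicted helix or strand.

    Over positions where the prediction says H or E, the fraction whose
    model label matches. Neutral 0.5 if the prediction contains no H/E.
    """
    if len(ss_model) != len(ss_pred):
        raise ValueError(f"SS string lengths differ: {len(ss_model)} vs {len(ss_pred)}")
    sites = [(m, p) for m, p in zip(ss_model, ss_pred) if p in "HE"]
    if not sites:
        return IMPUTED_VALUE
    return float(np.mean([m == p for m, p in sites]))


def euclidean_compact_score(dist: np.ndarray, L: int) -> float:
    """EC: mean pairwise CA distance over the maximum extended span 3.8 (L-1)."""
    if L < 2:
        raise ValueError(f"need at least 2 residues, got {L}")
    iu = np.triu_indices(L, k=1)
    mean_pairwise = float(dist[iu].mean())
    return _clamp01(mean_pairwise / (MAX_CA_CA_SPAN * (L - 1)))


def assemble_feature_vector(
    model: ProteinModel,
    external: Optional[ExternalScores] = None,
    predictions: Optional[PredictionInputs] = None,
    config: FeatureSetConfig = FULL16,
    sasa: Optional[SasaResult] = None,
    ss_model: Optional[str] = None,
) -> FeatureVector:
    """Compute/collect every feature for one model and impute what is missing.

    Structural features come from the model itself (SASA and secondary
    structure are computed here unless supplied). External scores are
    normalized; prediction-dependent features need ``predictions``. Missing
    entries are imputed at 0.5 — missingness is never fatal.
    """
    keys = config.keys
    values: Dict[str, float] = {}
    prov: Dict[str, str] = {}
    need = set(keys)

    if need & {"SU", "EM", "ES", "SA"}:
        if sasa is None:
            sasa = shrake_rupley_sasa(model)
        if "SU" in need:
            values["SU"], prov["SU"] = surface_score(sasa, model), "computed"
        if "EM" in need:
            values["EM"], prov["EM"] = exposed_mass_score(sasa, model), "computed"
        if "ES" in need:
            values["ES"], prov["ES"] = exposed_surface_score(sasa, model), "computed"
        if "SA" in need:
            sa_pred = predictions.sa_pred if predictions else None
            if sa_pred is not None:
                values["SA"], prov["SA"] = sa_agreement_score(sasa, sa_pred), "computed"
            else:
                values["SA"], prov["SA"] = IMPUTED_VALUE, "imputed"

    if need & {"SS", "SP"}:
        if ss_model is None:
            ss_model = assign_secondary_structure(model)
        ss_pred = predictions.ss_pred if predictions else None
        if "SS" in need:
            if ss_pred is not None:
                values["SS"], prov["SS"] = ss_similarity_score(ss_model, ss_pred), "computed"
            else:
                values["SS"], prov["SS"] = IMPUTED_VALUE, "imputed"
        if "SP" in need:
            if ss_pred is not None:
                values["SP"], prov["SP"] = ss_penalty_score(ss_model, ss_pred), "computed"
            else:
                values["SP"], prov["SP"] = IMPUTED_VALUE, "imputed"

    if "EC" in need:
        values["EC"], prov["EC"] = (
            euclidean_compact_score(distance_matrix(model), model.length),
            "computed",
        )

    ext_values: Dict[str, float] = {}
    if external is not None:
        ext_values.update(normalize_energy_scores(external, model.length))
        ext_values.update(normalize_auxiliary_energy_scores(external, model.length))
    for key in keys:
        if key in values:
            continue
        if key in ext_values:
            values[key], prov[key] = ext_values[key], "external"
        else:
            values[key], prov[key] = IMPUTED_VALUE, "imputed"

    ordered = {k: values[k] for k in keys}
    return FeatureVector(model_id=model.model_id, config=config, values=ordered, provenance=prov)


def feature_table(vectors: Iterable[FeatureVector]) -> "pandas.DataFrame":  # noqa: F821
    """Feature vectors as a DataFrame (model id index, ordered feature columns)."""
    import pandas as pd

    vectors = list(vectors)
    if not vectors:
        raise ValueError("no feature vectors")
    keys = vectors[0].config.keys
    rows = {v.model_id: [v.values[k] for k in keys] for v in vectors}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(keys)).rename_axis("model")
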