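"""Synthetic fixtures: ideal-geometry natives, noise-graded decoy pools and
feature datasets with a known feature-to-quality mapping.

The generator exists so the whole pipeline — parsing, features, training,
evaluation — runs end-to-end with no external data. Natives are ideal
backbones built from template dihedrals; decoys add isotropic Gaussian
coordinate noise (then a random rigid re-orientation), which yields pools
whose true GDT-TS/TM-score/RMSD degrade monotonically with the noise scale.
External tool scores can be emulated by inverting the feature normalization
maps on a noisy copy of the true quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from modelqa import features as F
from modelqa.qa_metrics import gdt_ts, rmsd, tm_score
from modelqa.structure_model import ExternalScores, ModelPool, ProteinModel, Residue

# Ideal backbone geometry (Å / degrees): Engh–Huber-like standard values.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

TEMPLATE_DIHEDRALS: Dict[str, Tuple[float, float]] = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    # Left-handed region: outside both the helix and strand windows.
    "coil": (65.0, 35.0),
}

DEFAULT_SIGMA_GRID = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class SimConfig:
    """Parameters of a simulated decoy experiment."""

    L: int = 30
    n_decoys: int = 20
    sigmas: Sequence[float] = DEFAULT_SIGMA_GRID
    seed: int = 0
    template: str = "helix"
    with_external: bool = True
    external_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.L < 5:
            raise ValueError("L must be >= 5")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("noise levels must be >= 0")
        if self.template not in {"helix", "strand", "coil", "mixed"}:
            raise ValueError(f"unknown template {self.template!r}")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF atom placement: position d given three predecessors and internal coords."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            -bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _template_phi_psi(config: SimConfig, rng: np.random.Generator) -> List[Tuple[float, float]]:
    if config.template != "mixed":
        return [TEMPLATE_DIHEDRALS[config.template]] * config.L
    # Mixed: alternating helix / strand segments joined by 2-residue coil linkers.
    out: List[Tuple[float, float]] = []
    kinds = ["helix", "strand"]
    ki = 0
    while len(out) < config.L:
        seg_len = int(rng.integers(4, 9))
        out.extend([TEMPLATE_DIHEDRALS[kinds[ki % 2]]] * seg_len)
        out.extend([TEMPLATE_DIHEDRALS["coil"]] * 2)
        ki += 1
    return out[: config.L]


def generate_native(config: SimConfig) -> ProteinModel:
    """Build an ideal-geometry backbone (N, CA, C per residue) from template dihedrals.

    Deterministic given the seed: the sequence is drawn uniformly over the
    20 amino acids and the chain is grown residue-by-residue with standard
    bond lengths/angles, trans peptide bonds and the template's phi/psi.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = sorted(F.RESIDUE_MASS.keys() - {"X"})
    sequence = "".join(rng.choice(alphabet) for _ in range(config.L))
    phi_psi = _template_phi_psi(config, rng)

    coords: List[Dict[str, np.ndarray]] = []
    # First residue placed explicitly.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, config.L):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues = [
        Residue(index=i + 1, aa=sequence[i], atoms=coords[i]) for i in range(config.L)
    ]
    return ProteinModel(model_id=f"native_{config.template}_L{config.L}", residues=residues)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def perturb_model(native: ProteinModel, sigma: float, model_id: str,
                  rng: np.random.Generator) -> ProteinModel:
    """Add i.i.d. Gaussian noise N(0, sigma^2) per atom coordinate, then re-orient."""
    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)
    residues = []
    for r in native.residues:
        atoms = {
            name: rot @ (xyz + rng.normal(0.0, sigma, size=3)) + trans
            for name, xyz in r.atoms.items()
        }
        residues.append(Residue(index=r.index, aa=r.aa, atoms=atoms))
    return ProteinModel(model_id=model_id, residues=residues)


def synthesize_external_scores(
    quality: float, L: int, rng: np.random.Generator, noise: float = 0.05
) -> ExternalScores:
    """Emulate raw external tool outputs consistent with a known quality.

    A noisy copy of the true quality is pushed through the inverse of each
    feature normalization map, so that normalizing the emitted raw scores
    approximately recovers the quality. This gives the synthetic pools the
    known feature-to-quality structure real energy scores carry.
    """
    def noisy() -> float:
        return float(np.clip(quality + rng.normal(0.0, noise), 0.0, 1.0))

    values = {
        "dfire2": -noisy() * F.ENERGY_NORM_DFIRE2 * L,
        "rwplus": -noisy() * F.ENERGY_NORM_RWPLUS * L,
        "rf_cb_srs_od": F.RF_OFFSET - noisy() * (F.RF_BASE + F.RF_SLOPE * L),
        "dope": -noisy() * F.ENERGY_NORM_DOPE * L,
        "goap": -noisy() * F.ENERGY_NORM_GOAP * L,
        "opus": -noisy() * F.ENERGY_NORM_OPUS * L,
        "proq2": noisy(),
        "modelevaluator": noisy(),
        "qprob": noisy(),
    }
    return ExternalScores(values=values)


def generate_decoys(native: ProteinModel, config: SimConfig) -> ModelPool:
    """Noise-graded decoy pool: ``n_decoys`` models per noise level sigma.

    True qualities are computable against the bundled native; when
    ``config.with_external`` is set, per-model raw external scores are
    synthesized from the true GDT-TS so the full 16-feature pipeline has
    informative inputs.
    """
    rng = np.random.default_rng(config.seed + 1)
    models: List[ProteinModel] = []
    external: Dict[str, ExternalScores] = {}
    for si, sigma in enumerate(config.sigmas):
        for di in range(config.n_decoys):
            mid = f"decoy_s{si}_{di:03d}"
            decoy = perturb_model(native, sigma, mid, rng)
            models.append(decoy)
            if config.with_external:
                q = gdt_ts(decoy, native)
                external[mid] = synthesize_external_scores(
                    q, native.length, rng, noise=config.external_noise
                )
    return ModelPool(
        target_id=native.model_id, models=models, native=native, external=external
    )


def pool_true_scores(pool: ModelPool) -> Dict[str, Dict[str, float]]:
    """True GDT-TS / TM-score / RMSD of every pool model against the native."""
    if pool.native is None:
        raise ValueError("pool has no native structure")
    out: Dict[str, Dict[str, float]] = {}
    for m in pool.models:
        out[m.model_id] = {
            "gdt_ts": gdt_ts(m, pool.native),
            "tm_score": tm_score(m, pool.native),
            "rmsd": rmsd(m, pool.native),
        }
    return out


def pool_feature_dataset(config: SimConfig):
    """Simulate a pool and turn it into a supervised feature dataset.

    Builds a native, a noise-graded decoy pool with synthetic external
    scores, and per-decoy 16-feature vectors. The SS/SA "predictions" are
    derived from the native (emulating a sequence-based predictor that is
    right about the native state), so prediction-agreement features degrade
    with decoy noise just as they do for real decoys. Targets are true
    GDT-TS against the native.

    Returns ``(X, y, model_ids, pool, native)``.
    """
    from modelqa.features import assemble_feature_vector
    from modelqa.geometry import assign_secondary_structure, shrake_rupley_sasa
    from modelqa.structure_model import PredictionInputs

    native = generate_native(config)
    pool = generate_decoys(native, config)
    ss_pred = assign_secondary_structure(native)
    sa_pred = "".join("e" if e else "b" for e in shrake_rupley_sasa(native).exposed)
    predictions = PredictionInputs(ss_pred=ss_pred, sa_pred=sa_pred)
    X, y, ids = [], [], []
    for m in pool.models:
        fv = assemble_feature_vector(
            m, external=pool.external.get(m.model_id), predictions=predictions
        )
        X.append(fv.as_array())
        y.append(gdt_ts(m, native))
        ids.append(m.model_id)
    return np.array(X), np.array(y), ids, pool, native


TARGET_CLAMP = (0.01, 0.99)  # avoid sigmoid saturation during fine-tuning


def _generating_function(n_features: int, informative: Tuple[int, int]) -> Callable:
    i, j = informative

    def f(X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-6.0 * (X[:, i] + X[:, j] - 1.0)))

    return f


def generate_feature_dataset(
    n: int,
    noise: float = 0.05,
    seed: int = 0,
    n_features: int = 16,
    informative: Tuple[int, int] = (0, 1),
):
    """Feature matrix in [0,1]^(n x m) with targets from a known monotone map.

    Features are i.i.d. uniform; the target is a sigmoid of the sum of the
    two informative features plus Gaussian noise, clamped to [0.01, 0.99].
    Returns ``(X, y, generating_function)`` so tests can check the noiseless
    mapping independently.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, n_features))
    f = _generating_function(n_features, informative)
    y = f(X) + rng.normal(0.0, noise, size=n)
    y = np.clip(y, *TARGET_CLAMP)
    return X, y, f
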