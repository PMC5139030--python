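"""Coordinate-level primitives.

Optimal rigid superposition (Kabsch), Shrake–Rupley solvent-accessible
surface area with deterministic Fibonacci sphere sampling, a dihedral-window
secondary-structure assigner, and CA–CA distance matrices. Everything here
is deterministic and invariant under rigid-body transforms of the input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.spatial.distance import cdist

from modelqa.structure_model import ProteinModel

# van der Waals radii (Å) by element; fallback 1.7 (carbon-like).
ATOM_RADII: Dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_ATOM_RADIUS = 1.70
# Pseudo-atom radius for CA-only models (one sphere per residue).
CA_ONLY_RADIUS = 2.00

# Theoretical maximum accessible surface area per residue (Å²), Tien et al. 2013.
MAX_ASA: Dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 197.0,
}

EXPOSURE_THRESHOLD = 0.25  # relative accessibility at/above which a residue is "exposed"


@dataclass
class Superposition:
    """Least-squares rigid transform mapping coordinates b onto a: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SasaResult:
    """Per-residue solvent accessibility.

    ``absolute`` is the summed atomic SASA (Å²), ``relative`` is absolute
    divided by the residue's reference maximum (clamped to [0,1]), and
    ``exposed`` flags residues with relative accessibility >= 0.25.
    """

    absolute: np.ndarray
    relative: np.ndarray
    exposed: np.ndarray
    ca_only: bool = False


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal rigid superposition of point set b onto point set a.

    Returns the rotation (proper, det=+1) and translation minimizing the
    RMSD between ``R b + t`` and ``a``, together with that RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes must match and be (n, 3): {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a0 = a - cen_a
    b0 = b - cen_b
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cen_a - rotation @ cen_b
    diff = b0 @ rotation.T - a0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _collect_atoms(model: ProteinModel):
    """Flatten atoms to (coords, radii, residue_index); CA-only models get pseudo-atoms."""
    heavy = []
    for ri, res in enumerate(model.residues):
        for name, xyz in res.atoms.items():
            if name.strip().upper().startswith("H"):
                continue
            heavy.append((ri, name, xyz))
    ca_only = all(name == "CA" for _, name, _ in heavy)
    coords = np.array([xyz for _, _, xyz in heavy], dtype=float)
    if ca_only:
        radii = np.full(len(heavy), CA_ONLY_RADIUS)
    else:
        radii = np.array(
            [ATOM_RADII.get(name.strip()[0].upper(), DEFAULT_ATOM_RADIUS) for _, name, _ in heavy]
        )
    res_idx = np.array([ri for ri, _, _ in heavy], dtype=int)
    return coords, radii, res_idx, ca_only


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Express coordinates in a rotation/translation-independent frame.

    Axes are the principal axes of the coordinate cloud; each axis sign is
    fixed by the sign of the third moment along it (falling back to the
    coordinate of the point farthest from the centroid), and handedness is
    made right-handed.
    """
    centered = coords - coords.mean(axis=0)
    if len(centered) < 3:
        return centered
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    for k in range(3):
        s = float((proj[:, k] ** 3).sum())
        if abs(s) < 1e-9:
            far = int(np.argmax(np.linalg.norm(centered, axis=1)))
            s = float(proj[far, k])
        if s < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return centered @ vecs


def shrake_rupley_sasa(
    model: ProteinModel, probe_radius: float = 1.4, n_points: int = 92
) -> SasaResult:
    """Shrake–Rupley SASA: sphere-point sampling of each atom's probe surface.

    For each heavy atom, ``n_points`` quasi-uniform points are placed on the
    probe-inflated sphere; points inside any neighbouring atom's inflated
    sphere are occluded. Atomic areas are summed per residue. CA-only models
    fall back to one 2.0 Å pseudo-atom per residue (approximate; a warning
    is emitted).
    """
    coords, radii, res_idx, ca_only = _collect_atoms(model)
    if coords.size == 0:
        raise ValueError(f"model {model.model_id}: no atoms")
    if ca_only:
        warnings.warn(
            f"model {model.model_id}: CA-only model, SASA uses per-residue pseudo-atoms",
            stacklevel=2,
        )
    # Work in a canonical molecule-local frame (PCA axes, signs fixed by the
    # third moment) so the fixed sampling directions rotate with the molecule
    # and SASA is invariant under rigid-body transforms of the input.
    coords = _canonical_frame(coords)
    sphere = fibonacci_sphere(n_points)
    inflated = radii + probe_radius
    n_atoms = len(coords)
    atom_area = np.zeros(n_atoms)
    # Neighbour lists via pairwise distances; pools here are small (<1e4 atoms).
    d2 = cdist(coords, coords, metric="sqeuclidean")
    for i in range(n_atoms):
        ri = inflated[i]
        cutoff2 = (ri + inflated.max()) ** 2
        neigh = np.where((d2[i] < cutoff2) & (np.arange(n_atoms) != i))[0]
        pts = coords[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            rj2 = inflated[j] ** 2
            dj2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= dj2 > rj2
            if not accessible.any():
                break
        atom_area[i] = 4.0 * math.pi * ri * ri * accessible.sum() / n_points
    L = model.length
    absolute = np.zeros(L)
    np.add.at(absolute, res_idx, atom_area)
    ref = np.array([MAX_ASA.get(r.aa, MAX_ASA["X"]) for r in model.residues])
    relative = np.clip(absolute / ref, 0.0, 1.0)
    exposed = relative >= EXPOSURE_THRESHOLD
    return SasaResult(absolute=absolute, relative=relative, exposed=exposed, ca_only=ca_only)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(model: ProteinModel):
    """Per-residue (phi, psi) in degrees; None where undefined (termini/missing atoms)."""
    L = model.length
    phi = [None] * L
    psi = [None] * L
    res = model.residues

    def atom(i: int, name: str) -> Optional[np.ndarray]:
        return res[i].atoms.get(name)

    for i in range(L):
        n_i, ca_i, c_i = atom(i, "N"), atom(i, "CA"), atom(i, "C")
        if i > 0:
            c_prev = atom(i - 1, "C")
            if all(x is not None for x in (c_prev, n_i, ca_i, c_i)):
                phi[i] = dihedral(c_prev, n_i, ca_i, c_i)
        if i < L - 1:
            n_next = atom(i + 1, "N")
            if all(x is not None for x in (n_i, ca_i, c_i, n_next)):
                psi[i] = dihedral(n_i, ca_i, c_i, n_next)
    return phi, psi


def _in_helix_window(phi: float, psi: float) -> bool:
    return -100.0 < phi < -30.0 and -80.0 < psi < -5.0


def _in_strand_window(phi: float, psi: float) -> bool:
    return -170.0 < phi < -50.0 and (80.0 < psi < 180.0 or -180.0 <= psi < -170.0)


def assign_secondary_structure(model: ProteinModel) -> str:
    """3-state secondary structure {H, E, C} from backbone phi/psi windows.

    H requires a run of >= 4 consecutive residues in the helical window,
    E a run of >= 2 in the extended window; everything else (including
    termini, where a dihedral is undefined) is C. This is a deterministic
    geometric stand-in for a hydrogen-bond-based assigner; a precomputed
    DSSP string can be supplied instead wherever an SS string is consumed.
    """
    L = model.length
    have_backbone = all(
        {"N", "CA", "C"} <= set(r.atoms) for r in model.residues
    )
    if not have_backbone:
        warnings.warn(
            f"model {model.model_id}: incomplete backbone, secondary structure set to coil",
            stacklevel=2,
        )
        return "C" * L
    phi, psi = backbone_dihedrals(model)
    helix = [p is not None and q is not None and _in_helix_window(p, q) for p, q in zip(phi, psi)]
    strand = [p is not None and q is not None and _in_strand_window(p, q) for p, q in zip(phi, psi)]
    ss = ["C"] * L

    def mark_runs(flags, label, min_run):
        i = 0
        while i < L:
            if flags[i]:
                j = i
                while j < L and flags[j]:
                    j += 1
                if j - i >= min_run:
                    for k in range(i, j):
                        ss[k] = label
                i = j
            else:
                i += 1

    mark_runs(strand, "E", 2)
    mark_runs(helix, "H", 4)  # helix wins where windows could overlap on a run
    return "".join(ss)


def reduce_dssp_8_to_3(ss8: str) -> str:
    """Standard 8->3 state reduction: {H,G,I}->H, {E,B}->E, else C."""
    table = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}
    return "".join(table.get(c, "C") for c in ss8.upper())


def distance_matrix(model: ProteinModel) -> np.ndarray:
    """Symmetric L x L matrix of CA–CA Euclidean distances (Å)."""
    ca = model.ca_coords()
    return cdist(ca, ca)
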