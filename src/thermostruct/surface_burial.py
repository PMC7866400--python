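"""Solvent-accessible surface area (Shrake–Rupley), burial classification,
core-residue tallies, and dimer-interface area.

The sphere lattice is a deterministic golden-spiral point set. To make total
SASA invariant under rigid-body motion of the whole molecule, the lattice is
oriented in the molecule's principal-axis frame with a rotation-equivariant
sign convention (third-moment/skewness of the coordinate projections), so
the lattice co-rotates with the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import VDW_RADII, DEFAULT_VDW, MAX_ASA_GXG
from .structure_io import Structure, Residue

DEFAULT_PROBE = 1.4     # Å, water probe
DEFAULT_N_POINTS = 960
DEFAULT_BURIAL_THRESHOLD = 0.07  # relative accessibility below which a residue is buried


@dataclass
class SASAResult:
    per_atom: np.ndarray          # Å², hierarchy order
    per_residue: dict[tuple, float]  # residue key -> Å²
    total: float                  # Å²
    probe_radius: float
    n_sphere_points: int


@dataclass
class BurialClassification:
    rel_access: dict[tuple, float]   # residue key -> SASA / reference max
    labels: dict[tuple, str]         # 'buried' | 'exposed'
    threshold: float

    def is_buried(self, res: Residue) -> bool:
        return self.labels[res.key] == "buried"


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic unit-sphere lattice (golden-spiral), (n, 3)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _principal_frame(xyz: np.ndarray) -> np.ndarray:
    """Rotation matrix (rows = axes) of the principal-axis frame.

    Eigenvector signs are fixed by the third central moment of the
    projections (falling back to the centroid->farthest-atom direction),
    which co-rotates with the molecule; handedness is enforced last.
    """
    if len(xyz) < 2:
        return np.eye(3)
    c = xyz.mean(axis=0)
    X = xyz - c
    cov = X.T @ X / len(X)
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]  # descending eigenvalue order
    far = X[np.argmax(np.einsum("ij,ij->i", X, X))]
    for k in range(3):
        p = X @ V[:, k]
        skew = np.sum(p ** 3)
        if abs(skew) > 1e-8:
            if skew < 0:
                V[:, k] = -V[:, k]
        elif far @ V[:, k] < 0:
            V[:, k] = -V[:, k]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return V.T


def _atom_radius(element: str, default_radius: float | None) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using default vdW radius")
        r = default_radius if default_radius is not None else DEFAULT_VDW
    return r


def sasa_from_arrays(xyz: np.ndarray, radii: np.ndarray, probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_N_POINTS,
                     frame: np.ndarray | None = None) -> np.ndarray:
    """Per-atom Shrake–Rupley SASA (Å²) for raw coordinate/radius arrays.

    `frame` overrides the lattice orientation (rows = axes); by default the
    molecule's own principal-axis frame is used.
    """
    xyz = np.asarray(xyz, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(xyz)
    if frame is None:
        frame = _principal_frame(xyz)
    lattice = golden_spiral_points(n_points) @ frame
    ext = radii + probe
    tree = cKDTree(xyz)
    out = np.empty(n)
    max_ext = ext.max()
    for i in range(n):
        pts = xyz[i] + ext[i] * lattice
        neigh = [j for j in tree.query_ball_point(xyz[i], ext[i] + max_ext) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            exposed &= d2 > ext[j] ** 2
        out[i] = exposed.sum() / n_points * 4.0 * np.pi * ext[i] ** 2
    return out


def shrake_rupley(s: Structure, probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS,
                  default_radius: float | None = None,
                  frame: np.ndarray | None = None) -> SASAResult:
    """Shrake–Rupley SASA of all heavy atoms of a structure."""
    atoms = list(s.iter_atoms())
    if not atoms:
        raise ValueError("structure has no atoms")
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([_atom_radius(a.element, default_radius) for a in atoms])
    per_atom = sasa_from_arrays(xyz, radii, probe, n_points, frame=frame)
    per_residue: dict[tuple, float] = {}
    i = 0
    for r in s.iter_residues():
        k = len(r.atoms)
        per_residue[r.key] = float(per_atom[i:i + k].sum())
        i += k
    return SASAResult(per_atom, per_residue, float(per_atom.sum()), probe, n_points)


def classify_burial(s: Structure, sasa: SASAResult,
                    threshold: float = DEFAULT_BURIAL_THRESHOLD) -> BurialClassification:
    """Label residues buried/exposed by relative accessibility.

    Relative accessibility = residue SASA / Gly-X-Gly extended-state
    reference maximum for the residue type.
    """
    rel: dict[tuple, float] = {}
    labels: dict[tuple, str] = {}
    for r in s.iter_residues():
        ref = MAX_ASA_GXG.get(r.one_letter)
        if ref is None:
            raise KeyError(f"no reference max SASA for residue type {r.res_name!r}")
        ra = sasa.per_residue[r.key] / ref
        rel[r.key] = ra
        labels[r.key] = "buried" if ra < threshold else "exposed"
    return BurialClassification(rel, labels, threshold)


def core_residue_counts(s: Structure, burial: BurialClassification) -> dict:
    """Buried-residue tallies by type, plus buried-hydrophobic totals."""
    if s.n_residues == 0:
        raise ValueError("empty structure")
    by_type: dict[str, int] = {}
    hydrophobic = set("GAVLIPMFW")
    n_buried = n_buried_hydrophobic = 0
    for r in s.iter_residues():
        if burial.labels[r.key] == "buried":
            by_type[r.one_letter] = by_type.get(r.one_letter, 0) + 1
            n_buried += 1
            if r.one_letter in hydrophobic:
                n_buried_hydrophobic += 1
    n = s.n_residues
    return {
        "by_type": by_type,
        "n_buried": n_buried,
        "n_buried_hydrophobic": n_buried_hydrophobic,
        "buried_per_100": 100.0 * n_buried / n,
        "buried_hydrophobic_per_100": 100.0 * n_buried_hydrophobic / n,
    }


def interface_area(dimer: Structure, chain_a: str, chain_b: str,
                   probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS) -> dict:
    """Buried interface area between two chains, Å².

    Area = (SASA(A alone) + SASA(B alone) - SASA(AB)) / 2. Interface residues
    are those whose per-residue SASA drops by > 1 Å² upon complexation.
    """
    if not (dimer.has_chain(chain_a) and dimer.has_chain(chain_b)):
        raise ValueError("both chains must be present")
    sub = dimer.copy()
    sub.chains = [c for c in sub.chains if c.chain_id in (chain_a, chain_b)]
    # one shared lattice orientation (the complex's principal frame) makes
    # the separated-chain case cancel exactly
    shared_frame = _principal_frame(sub.coords())
    alone: dict[tuple, float] = {}
    total_alone = 0.0
    for cid in (chain_a, chain_b):
        solo = dimer.copy()
        solo.chains = [c for c in solo.chains if c.chain_id == cid]
        res = shrake_rupley(solo, probe, n_points, frame=shared_frame)
        alone.update(res.per_residue)
        total_alone += res.total
    complexed = shrake_rupley(sub, probe, n_points, frame=shared_frame)
    # lattice-orientation quadrature noise can push a zero-contact area
    # marginally negative; the physical quantity is nonnegative
    area = max(0.0, 0.5 * (total_alone - complexed.total))
    interface_residues = [
        key for key, a in alone.items()
        if a - complexed.per_residue[key] > 1.0
    ]
    return {"area": area, "interface_residues": interface_residues,
            "n_interface_residues": len(interface_residues)}
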