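"""Synthetic structures and trajectories with known ground truth.

These generators stand in for deposited X-ray structures and MD output so
every analysis stage is testable offline:

* ideal peptides with prescribed (φ, ψ) built from standard backbone
  geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å), including an
  antiparallel two-strand hairpin construction;
* minimal planted-interaction structures whose single interaction of a
  chosen class sits at a requested defining distance;
* pre-aligned fluctuation trajectories with per-residue Gaussian noise,
  two-state trajectories giving bimodal RMS histograms, and controlled
  loop-approach trajectories for occlusion analysis.

All randomness flows through numpy's default PCG64 generator seeded
explicitly, so fixtures are reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import ONE_TO_THREE, STANDARD_AA
from .structure_io import Structure, Chain, Residue, Atom
from .trajectory_analysis import Trajectory

A_PER_NM = 10.0

# ideal backbone geometry (Engh–Huber-style averages)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.6, 121.9, 120.8
_A_N_CA_CB = 110.5


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle b-c-d and dihedral a-b-c-d (NeRF)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return math.degrees(math.atan2(np.cross(b1, v) @ w, v @ w))


def _as_array(value, n, name) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    return arr


def build_ideal_peptide(sequence: str, phi=-57.0, psi=-47.0,
                        chain_id: str = "A", start_seq: int = 1,
                        translate=(0.0, 0.0, 0.0)) -> Structure:
    """Backbone (N, CA, C, O) + CB peptide with the requested torsions.

    phi/psi may be scalars or per-residue arrays (degrees); the ω torsion is
    fixed at 180°. Side chains are truncated at CB ("rotamer 1" to the first
    side-chain atom); the planted-interaction builders place full functional
    groups where a detector needs them.
    """
    seq = sequence.upper()
    if not seq or any(c not in STANDARD_AA for c in seq):
        raise ValueError("sequence must be non-empty standard one-letter codes")
    n = len(seq)
    phi = _as_array(phi, n, "phi")
    psi = _as_array(psi, n, "psi")

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C,
                              phi[i + 1])
    O = np.empty((n, 3))
    for i in range(n):
        nxt = N[i + 1] if i + 1 < n else place_atom(N[i], CA[i], C[i], _B_C_N,
                                                    _A_CA_C_N, psi[i])
        O[i] = place_atom(nxt, CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0)

    shift = np.asarray(translate, dtype=float)
    residues = []
    serial = 1
    for i, aa in enumerate(seq):
        key = (chain_id, start_seq + i, "")
        atoms = []
        for name, xyz in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O[i])):
            atoms.append(Atom(serial, name, name[0], "", xyz + shift, 1.0, key))
            serial += 1
        if aa != "G":
            cb = place_atom(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB, -122.6)
            atoms.append(Atom(serial, "CB", "C", "", cb + shift, 1.0, key))
            serial += 1
        residues.append(Residue(chain_id, start_seq + i, "", ONE_TO_THREE[aa],
                                atoms))
    return Structure("ideal-peptide", [Chain(chain_id, residues)])


def build_antiparallel_hairpin(strand_seq: str = "VTVTVT") -> Structure:
    """Two antiparallel extended strands (chains A and B) forming a sheet.

    The second strand is the first rotated 180° about the z axis (reversing
    its direction) and translated; the offset is chosen deterministically
    to maximize inter-strand N···O contacts at H-bonding distance.
    """
    s1 = build_ideal_peptide(strand_seq, phi=-139.0, psi=135.0, chain_id="A")
    xyz1 = s1.coords()
    n1 = np.array([r.coord("N") for r in s1.chain("A")])
    o1 = np.array([r.coord("O") for r in s1.chain("A")])

    rot = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    center = xyz1.mean(axis=0)

    def score(offset):
        t = np.asarray(offset)
        n2 = (n1 - center) @ rot.T + center + t
        o2 = (o1 - center) @ rot.T + center + t
        good = 0
        for p in n1:
            d = np.linalg.norm(o2 - p, axis=1)
            good += int(((d > 2.6) & (d < 3.2)).any())
        for p in o1:
            d = np.linalg.norm(n2 - p, axis=1)
            good += int(((d > 2.6) & (d < 3.2)).any())
        return good

    best = None
    for dy in np.arange(4.0, 5.8, 0.05):
        for dx in np.arange(-3.0, 3.0, 0.1):
            for dz in np.arange(-1.0, 1.01, 0.25):
                sc = score((dx, dy, dz))
                if best is None or sc > best[0]:
                    best = (sc, (dx, dy, dz))
    t = np.array(best[1])
    s2 = build_ideal_peptide(strand_seq, phi=-139.0, psi=135.0, chain_id="B")
    s2.set_coords((s2.coords() - center) @ rot.T + center + t)
    merged = Structure("hairpin", [s1.chains[0], s2.chains[0]])
    return merged


# --- planted interactions -------------------------------------------------

PLANT_KINDS = ("hydrophobic", "hbond", "hbond_s", "salt_bridge", "pi_pi",
               "cation_pi", "pi_sulfur", "disulfide")


def _mini_residue(chain_id, seq_num, res_name, atom_spec) -> Residue:
    """Residue from [(name, element, xyz), ...]."""
    key = (chain_id, seq_num, "")
    atoms = [Atom(i + 1, name, el, "", np.asarray(xyz, dtype=float), 1.0, key)
             for i, (name, el, xyz) in enumerate(atom_spec)]
    return Residue(chain_id, seq_num, "", res_name, atoms)


def _ring_atoms(center, normal, names, radius=1.39):
    """Planar ring atom positions around a center, perpendicular to normal."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ normal) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    k = len(names)
    out = []
    for i, name in enumerate(names):
        ang = 2 * math.pi * i / k
        out.append((name, name[0],
                    np.asarray(center) + radius * (math.cos(ang) * u + math.sin(ang) * v)))
    return out


def plant_interaction(kind: str, distance: float) -> Structure:
    """Minimal two-residue structure with one planted interaction.

    The defining distance of the requested kind equals `distance` (Å); the
    two residues are non-adjacent in sequence (seq 1 and 5 of chain A) and
    scaffold atoms are kept far enough away not to add contacts.
    """
    d = float(distance)
    if d <= 0:
        raise ValueError("distance must be positive")
    far = 8.0  # CA offset keeping scaffold atoms out of every cutoff
    x = np.array([1.0, 0.0, 0.0])

    if kind == "hydrophobic":
        ra = _mini_residue("A", 1, "LEU", [("CA", "C", (-far, 0, 0)),
                                           ("CD1", "C", (0, 0, 0))])
        rb = _mini_residue("A", 5, "LEU", [("CA", "C", (d + far, 0, 0)),
                                           ("CD1", "C", (d, 0, 0))])
    elif kind == "hbond":
        ra = _mini_residue("A", 1, "SER", [("CA", "C", (-far, 0, 0)),
                                           ("OG", "O", (0, 0, 0))])
        rb = _mini_residue("A", 5, "THR", [("CA", "C", (d + far, 0, 0)),
                                           ("OG1", "O", (d, 0, 0))])
    elif kind == "hbond_s":
        ra = _mini_residue("A", 1, "SER", [("CA", "C", (-far, 0, 0)),
                                           ("OG", "O", (0, 0, 0))])
        rb = _mini_residue("A", 5, "MET", [("CA", "C", (d + far, 0, 0)),
                                           ("SD", "S", (d, 0, 0))])
    elif kind == "salt_bridge":
        ra = _mini_residue("A", 1, "ASP", [("CA", "C", (-far, 0, 0)),
                                           ("OD1", "O", (0, 0, 0))])
        rb = _mini_residue("A", 5, "LYS", [("CA", "C", (d + far, 0, 0)),
                                           ("NZ", "N", (d, 0, 0))])
    elif kind == "pi_pi":
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring_a = _ring_atoms((0, 0, 0), x, names)
        ring_b = _ring_atoms((d, 0, 0), x, names)
        ra = _mini_residue("A", 1, "PHE", [("CA", "C", (-far, 0, 0))] + ring_a)
        rb = _mini_residue("A", 5, "PHE", [("CA", "C", (d + far, 0, 0))] + ring_b)
    elif kind == "cation_pi":
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring_a = _ring_atoms((0, 0, 0), x, names)
        ra = _mini_residue("A", 1, "PHE", [("CA", "C", (-far, 0, 0))] + ring_a)
        rb = _mini_residue("A", 5, "LYS", [("CA", "C", (d + far, 0, 0)),
                                           ("NZ", "N", (d, 0, 0))])
    elif kind == "pi_sulfur":
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring_a = _ring_atoms((0, 0, 0), x, names)
        ra = _mini_residue("A", 1, "PHE", [("CA", "C", (-far, 0, 0))] + ring_a)
        rb = _mini_residue("A", 5, "MET", [("CA", "C", (d + far, 0, 0)),
                                           ("SD", "S", (d, 0, 0))])
    elif kind == "disulfide":
        ra = _mini_residue("A", 1, "CYS", [("CA", "C", (-far, 0, 0)),
                                           ("SG", "S", (0, 0, 0))])
        rb = _mini_residue("A", 5, "CYS", [("CA", "C", (d + far, 0, 0)),
                                           ("SG", "S", (d, 0, 0))])
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")

    s = Structure(f"planted-{kind}", [Chain("A", [ra, rb])])
    # non-bonded clash check between the two residues (covalent geometry
    # within a residue is allowed to be short, e.g. ring bonds at 1.39 Å)
    from scipy.spatial.distance import cdist
    xa = np.array([a.coords for a in ra.atoms])
    xb = np.array([a.coords for a in rb.atoms])
    if cdist(xa, xb).min() < 1.5:
        raise ValueError("unrealizable geometry: atom clash below 1.5 Å")
    return s


def mini_homolog_pair() -> dict:
    """A deterministic stable/floppy mini-homolog pair with ground truth.

    Two helix–loop–helix–loop–helix proteins sharing the same fold: the
    "stable" homolog has short loops and a uniformly rigid fluctuation
    profile, the "floppy" one has an extended first surface loop carrying a
    5x larger fluctuation amplitude adjacent to the active site. Serves as
    the offline stand-in for a thermophilic/psychrophilic structure pair.
    """
    helix = (-57.0, -47.0)
    coil = (-80.0, 150.0)

    def torsions(segments):
        phi, psi = [], []
        for length, (p, q) in segments:
            phi += [p] * length
            psi += [q] * length
        return phi, psi

    stable_seq = "SLKELFAEKL" + "GSNG" + "AVIRELMEKI" + "GDKG" + "ALYEIAKL"
    stable_phi, stable_psi = torsions(
        [(10, helix), (4, coil), (10, helix), (4, coil), (8, helix)])
    floppy_seq = "SLKELFAEKL" + "GSNGESGKGSDG" + "AVIRELMEKI" + "GDKG" + "ALYEIAKL"
    floppy_phi, floppy_psi = torsions(
        [(10, helix), (12, coil), (10, helix), (4, coil), (8, helix)])

    stable = build_ideal_peptide(stable_seq, stable_phi, stable_psi)
    stable.id = "stable-homolog"
    floppy = build_ideal_peptide(floppy_seq, floppy_phi, floppy_psi)
    floppy.id = "floppy-homolog"

    sigma_stable = [0.03] * len(stable_seq)
    sigma_floppy = [0.03] * len(floppy_seq)
    for i in range(10, 22):        # the extended surface loop
        sigma_floppy[i] = 0.15

    return {
        "stable": {
            "structure": stable, "sigma_nm": sigma_stable,
            "active_site": [("A", 19), ("A", 21)],
            "floppy_loop_span": (11, 14),
            "t_m": 95.0, "t_opt": 80.0, "class": "thermophilic",
        },
        "floppy": {
            "structure": floppy, "sigma_nm": sigma_floppy,
            "active_site": [("A", 27), ("A", 29)],
            "floppy_loop_span": (11, 22),
            "t_m": 52.0, "t_opt": 28.0, "class": "psychrophilic",
        },
    }


# --- trajectory generators ------------------------------------------------


def _per_atom_sigma(ref: Structure, sigma_profile_nm) -> np.ndarray:
    residues = list(ref.iter_residues())
    sig = np.broadcast_to(np.asarray(sigma_profile_nm, dtype=float),
                          (len(residues),))
    if np.any(sig < 0):
        raise ValueError("sigma must be nonnegative")
    out = []
    for r, s_nm in zip(residues, sig):
        out.extend([s_nm * A_PER_NM] * len(r.atoms))
    return np.array(out)


def _random_rigid_motion(rng) -> tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    R = np.array([
        [1 - 2 * (yq * yq + zq * zq), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
        [2 * (xq * yq + zq * w), 1 - 2 * (xq * xq + zq * zq), 2 * (yq * zq - xq * w)],
        [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq * xq + yq * yq)],
    ])
    t = rng.uniform(-5.0, 5.0, size=3)
    return R, t


def fluctuation_trajectory(ref: Structure, sigma_profile_nm, n_frames: int,
                           seed: int = 0, prealigned: bool = True,
                           dt_ps: float = 10.0):
    """Gaussian fluctuation about a reference structure.

    Each frame adds isotropic per-coordinate noise with the owning residue's
    σ (nm). With prealigned=False an additional random rigid motion is
    applied per frame. Returns (Trajectory, ground_truth dict).
    """
    rng = np.random.default_rng(seed)
    sig = _per_atom_sigma(ref, sigma_profile_nm)
    base = ref.coords()
    frames = np.empty((n_frames, len(base), 3))
    for f in range(n_frames):
        xyz = base + rng.normal(size=base.shape) * sig[:, None]
        if not prealigned:
            R, t = _random_rigid_motion(rng)
            xyz = xyz @ R.T + t
        frames[f] = xyz
    truth = {
        "kind": "fluctuation-trajectory",
        "seed": seed,
        "prealigned": prealigned,
        "sigma_nm": list(np.broadcast_to(np.asarray(sigma_profile_nm, float),
                                         (ref.n_residues,))),
    }
    return Trajectory.from_frames(ref, frames, dt_ps), truth


def two_state_trajectory(ref_a: Structure, ref_b: Structure, p_a: float,
                         n_frames: int, within_sigma_nm: float = 0.01,
                         seed: int = 0, dt_ps: float = 10.0):
    """Frames drawn from two conformers with Bernoulli(p_a) state choice.

    Returns (Trajectory, labels) where labels[f] is 0 for state A, 1 for B.
    """
    if ref_a.n_atoms != ref_b.n_atoms:
        raise ValueError("conformer topologies differ in atom count")
    if not 0.0 <= p_a <= 1.0:
        raise ValueError("p_a must be in [0, 1]")
    rng = np.random.default_rng(seed)
    A, B = ref_a.coords(), ref_b.coords()
    labels = (rng.random(n_frames) >= p_a).astype(int)
    sig = within_sigma_nm * A_PER_NM
    frames = np.empty((n_frames, len(A), 3))
    for f in range(n_frames):
        base = B if labels[f] else A
        frames[f] = base + rng.normal(size=base.shape) * sig
    return Trajectory.from_frames(ref_a, frames, dt_ps), labels


def _loop_site_atoms(ref: Structure, loop_residues, site_residues):
    keys_loop = set(loop_residues)
    keys_site = set(site_residues)
    loop_idx, site_idx = [], []
    i = 0
    for r in ref.iter_residues():
        ident = (r.chain_id, r.seq_num)
        for _a in r.atoms:
            if ident in keys_loop:
                loop_idx.append(i)
            if ident in keys_site:
                site_idx.append(i)
            i += 1
    if not loop_idx or not site_idx:
        raise ValueError("loop or active-site residues not found in topology")
    return np.array(loop_idx), np.array(site_idx)


def approach_trajectory(ref: Structure, loop_residues, site_residues,
                        d_start_nm: float, d_end_nm: float, n_frames: int,
                        crossing_frame: int | None = None,
                        threshold_nm: float | None = None,
                        noise_nm: float = 0.0, seed: int = 0,
                        dt_ps: float = 10.0):
    """Loop rigidly translated toward the active site.

    The minimum loop-to-site heavy-atom distance follows a linear schedule
    d_start → d_end over the frames; when crossing_frame and threshold_nm
    are given the schedule is piecewise linear so the distance reaches the
    threshold exactly at crossing_frame. Residues are (chain_id, seq_num)
    pairs. Returns (Trajectory, ground_truth dict).
    """
    if d_start_nm <= d_end_nm:
        raise ValueError("d_start must exceed d_end")
    if d_end_nm < 0.1:
        raise ValueError("d_end must be at least 0.1 nm")
    loop_idx, site_idx = _loop_site_atoms(ref, loop_residues, site_residues)
    base = ref.coords()
    rng = np.random.default_rng(seed)

    if crossing_frame is not None:
        if threshold_nm is None or not d_end_nm <= threshold_nm <= d_start_nm:
            raise ValueError("crossing_frame needs a threshold within "
                             "[d_end, d_start]")
        sched = np.empty(n_frames)
        cf = int(crossing_frame)
        sched[:cf + 1] = np.linspace(d_start_nm, threshold_nm, cf + 1)
        sched[cf:] = np.linspace(threshold_nm, d_end_nm, n_frames - cf)
    else:
        sched = np.linspace(d_start_nm, d_end_nm, n_frames)

    def min_dist(xyz):
        from scipy.spatial.distance import cdist
        return cdist(xyz[loop_idx], xyz[site_idx]).min()

    d0 = min_dist(base)
    # translation axis: from the closest loop atom toward the closest site atom
    from scipy.spatial.distance import cdist
    D = cdist(base[loop_idx], base[site_idx])
    ii, jj = np.unravel_index(np.argmin(D), D.shape)
    axis = base[site_idx[jj]] - base[loop_idx[ii]]
    axis /= np.linalg.norm(axis)

    frames = np.empty((n_frames, len(base), 3))
    for f in range(n_frames):
        target = sched[f] * A_PER_NM
        xyz = base.copy()
        shift = d0 - target
        for _ in range(4):  # correct for non-closest-pair geometry changes
            xyz[loop_idx] = base[loop_idx] + shift * axis
            err = min_dist(xyz) - target
            if abs(err) < 1e-4:
                break
            shift += err
        if noise_nm > 0:
            xyz += rng.normal(size=xyz.shape) * noise_nm * A_PER_NM
        frames[f] = xyz
    truth = {
        "kind": "approach-trajectory",
        "seed": seed,
        "planted_min_distance_nm": sched.tolist(),
        "crossing_frame": crossing_frame,
        "threshold_nm": threshold_nm,
    }
    return Trajectory.from_frames(ref, frames, dt_ps), truth
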