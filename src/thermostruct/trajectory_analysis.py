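"""Trajectory container and MD-derived metrics.

Implements the analysis side of a standard MD workflow on pre-computed
frames: Kabsch superposition, backbone RMSD series, per-residue RMSF,
mass-weighted radius of gyration, total-SASA series, and greedy
("gromos") conformational clustering of the fitted pairwise-RMSD matrix.

Coordinates are Å internally; trajectory metrics are reported in nm
(RMSD/RMSF/Rg) or nm² (SASA). Frame times are in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_MASSES, DEFAULT_MASS, BACKBONE_ATOMS
from .structure_io import Structure, parse_pdb, write_pdb, PDBFormatError
from .surface_burial import sasa_from_arrays, DEFAULT_PROBE, _atom_radius

A_PER_NM = 10.0


@dataclass
class Trajectory:
    topology: Structure
    frames: np.ndarray            # (F, N, 3) Å
    times: np.ndarray             # (F,) ps, strictly increasing
    atom_names: list[str] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)
    residue_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[0] == 0:
            raise ValueError("empty trajectory")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if len(self.times) != len(self.frames):
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.atom_names:
            self.atom_names = [a.name for a in self.topology.iter_atoms()]
            self.elements = [a.element for a in self.topology.iter_atoms()]
            ridx = []
            for i, r in enumerate(self.topology.iter_residues()):
                ridx.extend([i] * len(r.atoms))
            self.residue_index = np.array(ridx, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    def selection(self, which: str = "backbone") -> np.ndarray:
        """Boolean atom mask: 'backbone' (N,CA,C,O), 'ca', 'heavy', 'all'."""
        names = np.array(self.atom_names)
        elements = np.array(self.elements)
        if which == "backbone":
            return np.isin(names, BACKBONE_ATOMS)
        if which == "ca":
            return names == "CA"
        if which == "heavy":
            return elements != "H"
        if which == "all":
            return np.ones(self.n_atoms, dtype=bool)
        raise ValueError(f"unknown selection {which!r}")

    @classmethod
    def from_frames(cls, topology: Structure, frames: np.ndarray,
                    dt_ps: float = 10.0, t0_ps: float = 0.0) -> "Trajectory":
        frames = np.asarray(frames, dtype=float)
        times = t0_ps + dt_ps * np.arange(len(frames))
        return cls(topology, frames, times)

    def stride_frames(self, stride: int) -> np.ndarray:
        return np.arange(0, self.n_frames, max(1, int(stride)))


class TrajectoryFormatError(ValueError):
    pass


def read_trajectory(text: str, fmt: str = "pdb",
                    topology: Structure | None = None,
                    dt_ps: float = 10.0) -> Trajectory:
    """Read a multi-model PDB or XYZ frame series.

    For PDB input the first MODEL defines the topology (unless one is
    given); all frames must share its atom count. XYZ input requires an
    explicit topology for atom metadata. Times are uniform at dt_ps.
    """
    if fmt == "pdb":
        blocks: list[list[str]] = []
        current: list[str] | None = None
        saw_model = False
        for line in text.splitlines():
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current:
                    blocks.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM") :
                if current is None:
                    if saw_model:
                        continue
                    current = []
                    blocks.append(current)
                current.append(line)
        if current and current not in blocks:
            blocks.append(current)
        if not blocks:
            raise TrajectoryFormatError("no frames in trajectory input")
        top = topology or parse_pdb("\n".join(blocks[0]))
        n = top.n_atoms
        frames = np.empty((len(blocks), n, 3))
        for f, block in enumerate(blocks):
            coords = []
            for line in block:
                try:
                    coords.append((float(line[30:38]), float(line[38:46]),
                                   float(line[46:54])))
                except ValueError as exc:
                    raise TrajectoryFormatError(
                        f"bad coordinates in frame {f}") from exc
            if len(coords) != n:
                raise TrajectoryFormatError(
                    f"frame {f} has {len(coords)} atoms, topology has {n}")
            frames[f] = coords
        return Trajectory.from_frames(top, frames, dt_ps)
    if fmt == "xyz":
        if topology is None:
            raise ValueError("XYZ trajectories require an explicit topology")
        lines = text.splitlines()
        i = 0
        frames = []
        n_top = topology.n_atoms
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"expected atom count at line {i + 1}") from exc
            if n != n_top:
                raise TrajectoryFormatError(
                    f"frame {len(frames)} has {n} atoms, topology has {n_top}")
            rows = []
            for k in range(n):
                parts = lines[i + 2 + k].split()
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
            frames.append(rows)
            i += 2 + n
        if not frames:
            raise TrajectoryFormatError("no frames in trajectory input")
        return Trajectory.from_frames(topology, np.array(frames), dt_ps)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory_pdb(traj: Trajectory) -> str:
    """Serialize as a multi-model PDB."""
    out = []
    top = traj.topology.copy()
    for f in range(traj.n_frames):
        top.set_coords(traj.frames[f])
        out.append(f"MODEL     {f + 1:4d}")
        out.append(write_pdb(top, end=False).rstrip("\n"))
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


def write_xyz(traj: Trajectory, comment: str = "") -> str:
    lines = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"{comment} t={traj.times[f]:g} ps".strip())
        for el, xyz in zip(traj.elements, traj.frames[f]):
            lines.append(f"{el or 'X'} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    return "\n".join(lines) + "\n"


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None):
    """Optimal superposition of mobile onto reference.

    Returns (R, t, rmsd) with the proper rotation R (det +1) and translation
    t such that mobile @ R.T + t best matches reference in the weighted
    least-squares sense; rmsd in the input units.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    pc = (w[:, None] * P).sum(axis=0) / wsum
    qc = (w[:, None] * Q).sum(axis=0) / wsum
    P0, Q0 = P - pc, Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    return R, t, rmsd


def rmsd_series(traj: Trajectory, reference: np.ndarray | int = 0,
                selection: str | np.ndarray = "backbone") -> np.ndarray:
    """Per-frame fitted RMSD against a reference frame, nm."""
    mask = traj.selection(selection) if isinstance(selection, str) else selection
    if mask.sum() == 0:
        raise ValueError("empty selection")
    ref = traj.frames[reference][mask] if isinstance(reference, (int, np.integer)) \
        else np.asarray(reference, dtype=float)[mask]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, r = kabsch_fit(traj.frames[f][mask], ref)
        out[f] = r
    return out / A_PER_NM


@dataclass
class FlexibilityProfile:
    rmsf: np.ndarray              # per residue, nm
    per_atom_rmsf: np.ndarray     # per selected atom, nm
    reference: np.ndarray         # mean structure (selected atoms), Å
    residue_keys: list[tuple]
    temperature: float | None = None  # K, label only


def rmsf(traj: Trajectory, selection: str | np.ndarray = "ca",
         fit: bool = True, temperature: float | None = None) -> FlexibilityProfile:
    """Per-residue RMSF about the trajectory mean, nm.

    With fit=True each frame is superposed in two passes (fit to frame 0,
    rebuild the mean, refit to the mean). Per-residue values are taken at
    the CA atom of the selection (or the mean over the residue's selected
    atoms when no CA is selected).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mask = traj.selection(selection) if isinstance(selection, str) else selection
    if mask.sum() == 0:
        raise ValueError("empty selection")
    X = traj.frames[:, mask, :].copy()
    if fit:
        for _pass in range(2):
            ref = X[0] if _pass == 0 else X.mean(axis=0)
            for f in range(len(X)):
                R, t, _ = kabsch_fit(X[f], ref)
                X[f] = X[f] @ R.T + t
    mean = X.mean(axis=0)
    dev = X - mean
    per_atom = np.sqrt(np.einsum("fij,fij->i", dev, dev) / len(X)) / A_PER_NM

    ridx = traj.residue_index[mask]
    names = np.array(traj.atom_names)[mask]
    residues = list(traj.topology.iter_residues())
    per_res = np.empty(len(residues))
    for i in range(len(residues)):
        here = ridx == i
        if not here.any():
            per_res[i] = np.nan
            continue
        ca = here & (names == "CA")
        per_res[i] = per_atom[ca][0] if ca.any() else per_atom[here].mean()
    return FlexibilityProfile(per_res, per_atom, mean,
                              [r.key for r in residues], temperature)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration, nm."""
    x = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    if len(x) == 0 or m.sum() <= 0:
        raise ValueError("need at least one atom with positive mass")
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    d2 = np.einsum("ij,ij->i", x - com, x - com)
    return float(np.sqrt((m * d2).sum() / m.sum())) / A_PER_NM


def atom_masses(traj: Trajectory) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(el, DEFAULT_MASS) for el in traj.elements])


def rg_series(traj: Trajectory, stride: int = 1) -> np.ndarray:
    m = atom_masses(traj)
    idx = traj.stride_frames(stride)
    return np.array([radius_of_gyration(traj.frames[f], m) for f in idx])


@dataclass
class ClusterResult:
    assignments: np.ndarray       # cluster id per strided frame
    centers: list[int]            # medoid frame positions (strided index)
    frame_indices: np.ndarray     # original frame index of each strided frame
    rms_histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges nm, counts)
    rmsd_matrix: np.ndarray       # nm, strided frames

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def pairwise_rmsd_matrix(traj: Trajectory, selection="backbone",
                         frame_indices: np.ndarray | None = None) -> np.ndarray:
    mask = traj.selection(selection) if isinstance(selection, str) else selection
    idx = np.arange(traj.n_frames) if frame_indices is None else frame_indices
    X = traj.frames[:, mask, :]
    n = len(idx)
    M = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            _, _, r = kabsch_fit(X[idx[a]], X[idx[b]])
            M[a, b] = M[b, a] = r / A_PER_NM
    return M


def gromos_cluster(traj: Trajectory, cutoff: float = 0.5,
                   stride: int = 1, selection="backbone",
                   hist_bin_width: float = 0.02) -> ClusterResult:
    """Greedy RMSD clustering (the gromos algorithm).

    Repeatedly takes the frame with the most neighbors within `cutoff` nm
    (ties to the lowest frame index) as a cluster center and removes it
    with its neighbors. The RMS-matrix histogram is built from the upper
    triangle of the full strided matrix with `hist_bin_width` nm bins.
    """
    idx = traj.stride_frames(stride)
    if len(idx) == 0:
        raise ValueError("no frames after striding")
    M = pairwise_rmsd_matrix(traj, selection, idx)
    n = len(idx)
    within = M <= cutoff
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (within & remaining[None, :] & remaining[:, None]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(within[center] & remaining)[0]
        assignments[members] = cid
        centers.append(center)
        remaining[members] = False
        cid += 1
    tri = M[np.triu_indices(n, k=1)]
    upper = max(tri.max() if len(tri) else hist_bin_width, hist_bin_width)
    edges = np.arange(0.0, upper + hist_bin_width, hist_bin_width)
    counts_h, edges = np.histogram(tri, bins=edges)
    return ClusterResult(assignments, centers, idx, (edges, counts_h), M)


def sasa_series(traj: Trajectory, probe: float = DEFAULT_PROBE,
                n_points: int = 240, stride: int = 1) -> np.ndarray:
    """Per-strided-frame total SASA, nm²."""
    radii = np.array([_atom_radius(el, None) for el in traj.elements])
    idx = traj.stride_frames(stride)
    out = np.empty(len(idx))
    for k, f in enumerate(idx):
        out[k] = sasa_from_arrays(traj.frames[f], radii, probe, n_points).sum()
    return out / (A_PER_NM ** 2)


def stride_from_time(traj: Trajectory, stride_time_ps: float) -> int:
    """Convert a time stride (e.g. 5 ns = 5000 ps) to a frame stride."""
    if traj.n_frames < 2:
        return 1
    dt = float(traj.times[1] - traj.times[0])
    return max(1, int(round(stride_time_ps / dt)))
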