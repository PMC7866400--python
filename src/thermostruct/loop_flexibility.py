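"""Floppy-loop identification and active-site proximity/occlusion.

Loops (coil segments) are ranked by the mean RMSF of their member residues;
the top-ranked segments are the candidate "floppy" loops from which thermal
unfolding or active-site occlusion is most likely to start. Proximity to the
active site is the per-frame minimum heavy-atom distance between any loop
residue and any active-site residue, reported in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .secondary_structure import Loop
from .trajectory_analysis import Trajectory, FlexibilityProfile, A_PER_NM


@dataclass
class RankedLoop:
    loop: Loop
    mean_rmsf: float   # nm
    peak_rmsf: float   # nm
    rank: int
    primary: bool


@dataclass
class FloppyLoopReport:
    ranked: list[RankedLoop] = field(default_factory=list)
    active_site: list[tuple] = field(default_factory=list)

    @property
    def primary_loops(self) -> list[RankedLoop]:
        return [r for r in self.ranked if r.primary]


def rank_floppy_loops(loops: list[Loop], profile: FlexibilityProfile,
                      top_k: int = 3) -> FloppyLoopReport:
    """Rank loops by mean member-residue RMSF (descending).

    Ties break by peak RMSF, then by lower start index. The top_k loops are
    flagged primary.
    """
    if not loops:
        warnings.warn("no loops to rank")
        return FloppyLoopReport()
    key_to_idx = {k: i for i, k in enumerate(profile.residue_keys)}
    entries = []
    for lp in loops:
        idx = []
        for key, i in key_to_idx.items():
            if key[0] == lp.chain_id and lp.start.seq_num <= key[1] <= lp.end.seq_num:
                idx.append(i)
        if not idx:
            raise KeyError(
                f"loop {lp.chain_id}:{lp.residue_range} not covered by profile")
        vals = profile.rmsf[idx]
        entries.append((lp, float(np.nanmean(vals)), float(np.nanmax(vals))))
    order = sorted(range(len(entries)),
                   key=lambda i: (-entries[i][1], -entries[i][2],
                                  entries[i][0].start_index))
    report = FloppyLoopReport()
    for rank, i in enumerate(order, start=1):
        lp, mean_v, peak_v = entries[i]
        report.ranked.append(RankedLoop(lp, mean_v, peak_v, rank,
                                        rank <= top_k))
    report.ranked.sort(key=lambda r: r.rank)
    return report


def _residue_atom_indices(traj: Trajectory, idents: set[tuple]) -> np.ndarray:
    out = []
    i = 0
    for r in traj.topology.iter_residues():
        ident = (r.chain_id, r.seq_num)
        for a in r.atoms:
            if ident in idents and a.element != "H":
                out.append(i)
            i += 1
    return np.array(out, dtype=int)


def _loop_idents(loop: Loop | list) -> set[tuple]:
    if isinstance(loop, Loop):
        return {(loop.chain_id, s) for s in
                range(loop.start.seq_num, loop.end.seq_num + 1)}
    return set(loop)


def active_site_proximity(loop, active_site: list[tuple],
                          traj: Trajectory) -> dict:
    """Per-frame minimum loop-to-site heavy-atom distance, nm.

    `loop` is a Loop or a list of (chain_id, seq_num); `active_site` a list
    of (chain_id, seq_num). Returns {'series', 'min', 'mean',
    'closest_frame'}.
    """
    if not active_site:
        raise ValueError("active-site residue list is empty")
    loop_ids = _loop_idents(loop)
    site_ids = set(active_site)
    overlap = loop_ids & site_ids
    if overlap:
        warnings.warn(f"loop and active site share residues: {sorted(overlap)}")
    li = _residue_atom_indices(traj, loop_ids)
    si = _residue_atom_indices(traj, site_ids)
    if len(li) == 0 or len(si) == 0:
        raise ValueError("loop or active-site residues absent from topology")
    series = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        series[f] = cdist(traj.frames[f][li], traj.frames[f][si]).min()
    series /= A_PER_NM
    return {
        "series": series,
        "min": float(series.min()),
        "mean": float(series.mean()),
        "closest_frame": int(np.argmin(series)),
    }


def occlusion_flag(loop, active_site: list[tuple], traj: Trajectory,
                   approach_threshold: float,
                   equilibration_fraction: float = 0.1) -> tuple[bool, int | None]:
    """Whether the loop ever comes within `approach_threshold` nm of the site.

    Frames inside the initial equilibration window (default first 10%) are
    ignored. Returns (flag, first_occlusion_frame) with the frame index on
    the full trajectory, or None when never occluded.
    """
    if approach_threshold <= 0:
        raise ValueError("threshold must be positive")
    prox = active_site_proximity(loop, active_site, traj)
    start = int(np.floor(equilibration_fraction * traj.n_frames))
    series = prox["series"]
    hits = np.where(series[start:] < approach_threshold)[0]
    if len(hits) == 0:
        return False, None
    return True, int(start + hits[0])
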