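"""Three-state secondary-structure assignment and derived loop statistics.

Assignment follows the Kabsch–Sander (DSSP) rules on heavy-atom X-ray
coordinates: amide hydrogens are rebuilt at ideal geometry (H = N_i plus the
unit vector from O to C of the preceding residue), backbone H-bonds are
scored with the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and accepted below -0.5 kcal/mol. n-turns define 3/4/5-helices, bridge
patterns define strands, and the 8-state alphabet is reduced to 3 states:
{H, G, I} -> H, {E, B} -> E, else C.

Loops are maximal coil runs strictly between two non-coil elements; terminal
coil is reported separately (it proxies the disordered termini, not loops).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Structure, Residue

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0
_MIN_SEQ_SEP = 2  # |i-j| below this: no H-bond scored
_PEPTIDE_BOND_MAX = 2.5  # Å C(i)-N(i+1) distance implying chain continuity


@dataclass
class SSAssignment:
    """Per-chain 3-state strings plus the backbone H-bond list."""
    chain_ids: list[str]
    states: dict[str, str]                    # chain -> e.g. "CCHHHHCC"
    residues: dict[str, list[Residue]]        # chain -> residues in order
    hbonds: list[tuple[int, int]] = field(default_factory=list)  # (acceptor, donor) flat indices

    def state_string(self) -> str:
        return "".join(self.states[c] for c in self.chain_ids)

    def residue_states(self) -> list[tuple[Residue, str]]:
        out = []
        for c in self.chain_ids:
            out.extend(zip(self.residues[c], self.states[c]))
        return out


@dataclass
class Loop:
    chain_id: str
    start: Residue
    end: Residue
    length: int
    sequence: str
    start_index: int  # position within the chain (0-based)

    @property
    def residue_range(self) -> tuple[int, int]:
        return (self.start.seq_num, self.end.seq_num)


@dataclass
class HelixCapCensus:
    n_cap_acidic: int = 0
    n_cap_basic: int = 0
    c_cap_acidic: int = 0
    c_cap_basic: int = 0
    pro_at_ncap: int = 0
    pro_in_middle: int = 0
    n_helices: int = 0


def _backbone_frames(s: Structure):
    """Flat residue list with backbone coordinates, ideal H, and chain breaks."""
    residues: list[Residue] = []
    chain_of: list[int] = []
    for ci, chain in enumerate(s.chains):
        for r in chain.residues:
            residues.append(r)
            chain_of.append(ci)
    n = len(residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, r in enumerate(residues):
        xyz = [r.coord(a) for a in ("N", "CA", "C", "O")]
        if all(v is not None for v in xyz):
            N[i], CA[i], C[i], O[i] = xyz
            ok[i] = True
        else:
            warnings.warn(
                f"residue {r.res_name} {r.chain_id}{r.seq_num} lacks backbone "
                "atoms; forced to coil")
    # connectivity between consecutive flat positions
    connected = np.zeros(n, dtype=bool)  # connected[i]: i-1 -> i is a peptide bond
    for i in range(1, n):
        if chain_of[i] == chain_of[i - 1] and ok[i] and ok[i - 1]:
            connected[i] = np.linalg.norm(N[i] - C[i - 1]) < _PEPTIDE_BOND_MAX
    # ideal amide H: N + unit(C_prev - O_prev); absent for chain starts and Pro
    H = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for i in range(n):
        if ok[i] and connected[i] and residues[i].res_name != "PRO":
            d = C[i - 1] - O[i - 1]
            H[i] = N[i] + d / np.linalg.norm(d)
            has_h[i] = True
    return residues, chain_of, N, CA, C, O, H, ok, has_h, connected


def _hbond_energy(N_d, H_d, C_a, O_a) -> float:
    r_on = np.linalg.norm(O_a - N_d)
    r_ch = np.linalg.norm(C_a - H_d)
    r_oh = np.linalg.norm(O_a - H_d)
    r_cn = np.linalg.norm(C_a - N_d)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing/degenerate geometry
        return -9.9
    return _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_ss(s: Structure) -> SSAssignment:
    """Kabsch–Sander assignment reduced to 3 states (H/E/C)."""
    residues, chain_of, N, CA, C, O, H, ok, has_h, connected = _backbone_frames(s)
    n = len(residues)
    states = np.full(n, "C", dtype="<U1")

    # hbond[a][d]: C=O of a accepts from N-H of d
    hb: set[tuple[int, int]] = set()
    if n >= 4:
        # candidate pruning on CA distance (< 9 Å covers all real H-bonds)
        ca_ok = np.where(ok)[0]
        for a in ca_ok:
            for d in ca_ok:
                if abs(a - d) < _MIN_SEQ_SEP and chain_of[a] == chain_of[d]:
                    continue
                if a == d or not has_h[d]:
                    continue
                if np.linalg.norm(CA[a] - CA[d]) > 9.0:
                    continue
                if _hbond_energy(N[d], H[d], C[a], O[a]) < HBOND_ENERGY_CUTOFF:
                    hb.add((a, d))

    def same_run(i, j):
        """Residues i..j consecutive within one chain without breaks."""
        if not (0 <= i and j < n):
            return False
        return all(connected[k] for k in range(i + 1, j + 1))

    def turn(i, m):
        return same_run(i, i + m) and (i, i + m) in hb

    # helices: two consecutive n-turns; 4-helix has priority, then E, then G/I
    in_h4 = np.zeros(n, dtype=bool)
    in_g3 = np.zeros(n, dtype=bool)
    in_i5 = np.zeros(n, dtype=bool)
    for i in range(n):
        if turn(i - 1, 4) and turn(i, 4):
            in_h4[i:i + 4] = True
        if turn(i - 1, 3) and turn(i, 3):
            in_g3[i:i + 3] = True
        if turn(i - 1, 5) and turn(i, 5):
            in_i5[i:i + 5] = True

    # bridges (all bridge residues map to E under the 3-state reduction)
    in_e = np.zeros(n, dtype=bool)

    def hbond(a, d):
        return (a, d) in hb

    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or \
                   (hbond(j - 1, i) and hbond(i, j + 1))
            anti = (hbond(i, j) and hbond(j, i)) or \
                   (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
            if para or anti:
                in_e[i] = in_e[j] = True

    states[in_g3 | in_i5] = "H"
    states[in_e] = "E"
    states[in_h4] = "H"
    states[~ok] = "C"

    chain_ids = [c.chain_id for c in s.chains]
    out_states: dict[str, str] = {}
    out_res: dict[str, list[Residue]] = {}
    pos = 0
    for ci, chain in enumerate(s.chains):
        m = len(chain.residues)
        out_states[chain.chain_id] = "".join(states[pos:pos + m])
        out_res[chain.chain_id] = list(chain.residues)
        pos += m
    return SSAssignment(chain_ids, out_states, out_res, sorted(hb))


def write_state_strings(ss: SSAssignment) -> str:
    """Serialize as plain text, one 'chain<TAB>states' line per chain."""
    return "".join(f"{c}\t{ss.states[c]}\n" for c in ss.chain_ids)


def read_state_strings(text: str, s: Structure) -> SSAssignment:
    """Import an external 3-state assignment for a parsed structure.

    Accepts the write_state_strings format (chain<TAB>states per line);
    lets users reproduce statistics under a different assigner's output.
    """
    states: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        chain_id, _, state = line.partition("\t")
        states[chain_id] = state.strip().upper()
    chain_ids, residues = [], {}
    for chain in s.chains:
        cid = chain.chain_id
        if cid not in states:
            raise KeyError(f"no state string for chain {cid!r}")
        if len(states[cid]) != len(chain.residues):
            raise ValueError(
                f"chain {cid!r}: {len(states[cid])} states for "
                f"{len(chain.residues)} residues")
        if set(states[cid]) - set("HEC"):
            raise ValueError(f"chain {cid!r}: states must be H/E/C")
        chain_ids.append(cid)
        residues[cid] = list(chain.residues)
    return SSAssignment(chain_ids, states, residues)


def _coil_runs(state: str):
    """(start, end_exclusive) of maximal C runs."""
    runs = []
    i = 0
    while i < len(state):
        if state[i] == "C":
            j = i
            while j < len(state) and state[j] == "C":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def extract_loops(ss: SSAssignment, long_threshold: int = 10):
    """Loops (maximal interior coil runs) and counts.

    Returns (loops, counts) with counts = {'n_loops', 'n_long_loops',
    'terminal_coil': {chain: (n_term_len, c_term_len)}}.
    """
    loops: list[Loop] = []
    terminal: dict[str, tuple[int, int]] = {}
    for cid in ss.chain_ids:
        state = ss.states[cid]
        residues = ss.residues[cid]
        n_term = c_term = 0
        for i, j in _coil_runs(state):
            if i == 0:
                n_term = j - i
                continue
            if j == len(state):
                c_term = j - i
                continue
            seq = "".join(r.one_letter for r in residues[i:j])
            loops.append(Loop(cid, residues[i], residues[j - 1], j - i, seq, i))
        terminal[cid] = (n_term, c_term)
    counts = {
        "n_loops": len(loops),
        "n_long_loops": sum(1 for lp in loops if lp.length > long_threshold),
        "terminal_coil": terminal,
    }
    if not loops:
        warnings.warn("no interior loops found")
    return loops, counts


def _helix_runs(state: str):
    runs = []
    i = 0
    while i < len(state):
        if state[i] == "H":
            j = i
            while j < len(state) and state[j] == "H":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def helix_cap_census(s: Structure, ss: SSAssignment) -> HelixCapCensus:
    """Charge of single-residue helix caps and Pro placement within helices.

    N-cap: residue immediately preceding the first helical residue; C-cap:
    residue immediately following the last. Middle of a helix excludes one
    helical turn (3 residues) at each end.
    """
    acidic, basic = set("DE"), set("KRH")
    census = HelixCapCensus()
    for cid in ss.chain_ids:
        state = ss.states[cid]
        seq = "".join(r.one_letter for r in ss.residues[cid])
        for i, j in _helix_runs(state):
            census.n_helices += 1
            if i - 1 >= 0:
                aa = seq[i - 1]
                census.n_cap_acidic += aa in acidic
                census.n_cap_basic += aa in basic
                census.pro_at_ncap += aa == "P"
            if j < len(seq):
                aa = seq[j]
                census.c_cap_acidic += aa in acidic
                census.c_cap_basic += aa in basic
            middle = seq[i + 3:j - 3]
            census.pro_in_middle += middle.count("P")
    return census


def gly_pro_placement(seq: str, states: str) -> dict[str, dict[str, float | None]]:
    """Percent of all Gly (and of all Pro) falling in each SS state.

    Returns {'G': {'H': %, 'E': %, 'C': %}, 'P': {...}}; None when the
    residue type is absent from the sequence.
    """
    if len(seq) != len(states):
        raise ValueError("sequence and state string lengths differ")
    out: dict[str, dict[str, float | None]] = {}
    for aa in ("G", "P"):
        total = seq.count(aa)
        if total == 0:
            out[aa] = {"H": None, "E": None, "C": None}
            continue
        out[aa] = {
            st: 100.0 * sum(1 for a, x in zip(seq, states) if a == aa and x == st) / total
            for st in "HEC"
        }
    return out


def ss_content(ss: SSAssignment | str) -> dict[str, float]:
    """Percent helix/strand/coil and total structured content."""
    state = ss if isinstance(ss, str) else ss.state_string()
    n = len(state)
    if n == 0:
        raise ValueError("empty assignment")
    helix = 100.0 * state.count("H") / n
    strand = 100.0 * state.count("E") / n
    coil = 100.0 * state.count("C") / n
    return {"helix": helix, "strand": strand, "coil": coil,
            "total_SS": helix + strand}
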