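"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested loops over atoms/pairs, kept
deliberately separate from the package's implementations so that agreement
is a meaningful check.
"""

import math

from thermostruct.constants import (
    APOLAR_CONTACT, HBOND_SIDECHAIN_DONORS, HBOND_SIDECHAIN_ACCEPTORS,
    ACIDIC_O_ATOMS, BASIC_N_ATOMS, AROMATIC_RINGS, SULFUR_ATOMS,
)


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _residues(s):
    out = []
    for chain in s.chains:
        out.extend(chain.residues)
    return out


def _pair_key(ra, rb):
    return tuple(sorted([ra.key, rb.key]))


def brute_hydrophobic(s, cutoff=5.0):
    res = [r for r in _residues(s) if r.one_letter in APOLAR_CONTACT]
    pairs = set()
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            ra, rb = res[i], res[j]
            if ra.chain_id == rb.chain_id and abs(ra.seq_num - rb.seq_num) <= 1:
                continue
            hit = False
            for a in ra.sidechain_atoms():
                for b in rb.sidechain_atoms():
                    if _dist(a.coords, b.coords) <= cutoff:
                        hit = True
            if hit:
                pairs.add(_pair_key(ra, rb))
    return pairs


def _donor_atoms(r):
    out = []
    if r.one_letter != "P":
        a = r.get("N")
        if a is not None:
            out.append(("N", a, False))
    for name in HBOND_SIDECHAIN_DONORS.get(r.one_letter, ()):
        a = r.get(name)
        if a is not None:
            out.append((name, a, name.startswith("S")))
    return out


def _acceptor_atoms(r):
    out = []
    for name in ("O", "OXT"):
        a = r.get(name)
        if a is not None:
            out.append((name, a, False))
    for name in HBOND_SIDECHAIN_ACCEPTORS.get(r.one_letter, ()):
        a = r.get(name)
        if a is not None:
            out.append((name, a, name.startswith("S")))
    return out


def brute_hbonds(s, cutoff_on=3.5, cutoff_s=4.0):
    res = _residues(s)
    pairs = set()
    for rd in res:
        for ra in res:
            if rd.key == ra.key:
                continue
            adjacent = (rd.chain_id == ra.chain_id
                        and abs(rd.seq_num - ra.seq_num) <= 1)
            for dn, datom, dsulf in _donor_atoms(rd):
                for an, aatom, asulf in _acceptor_atoms(ra):
                    if adjacent and dn == "N" and an in ("O", "OXT"):
                        continue
                    cut = cutoff_s if (dsulf or asulf) else cutoff_on
                    if _dist(datom.coords, aatom.coords) <= cut:
                        pairs.add(_pair_key(rd, ra))
    return pairs


def brute_salt_bridges(s, cutoff=4.0):
    res = _residues(s)
    pairs = set()
    for ra in res:
        a_names = list(ACIDIC_O_ATOMS.get(ra.one_letter, ()))
        if ra.get("OXT") is not None:
            a_names.append("OXT")
        for rb in res:
            if ra.key == rb.key or rb.one_letter not in BASIC_N_ATOMS:
                continue
            for an in a_names:
                aa = ra.get(an)
                if aa is None:
                    continue
                for bn in BASIC_N_ATOMS[rb.one_letter]:
                    bb = rb.get(bn)
                    if bb is not None and _dist(aa.coords, bb.coords) <= cutoff:
                        pairs.add(_pair_key(ra, rb))
    return pairs


def _centroids(r):
    cents = []
    for ring in AROMATIC_RINGS.get(r.one_letter, ()):
        pts = [r.coord(n) for n in ring]
        if all(p is not None for p in pts):
            cents.append([sum(p[k] for p in pts) / len(pts) for k in range(3)])
    return cents


def brute_pi_pi(s, dmin=4.5, dmax=7.0):
    res = [r for r in _residues(s) if r.one_letter in AROMATIC_RINGS]
    pairs = set()
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            for ca in _centroids(res[i]):
                for cb in _centroids(res[j]):
                    if dmin <= _dist(ca, cb) <= dmax:
                        pairs.add(_pair_key(res[i], res[j]))
    return pairs


def brute_cation_pi(s, cutoff=6.0):
    res = _residues(s)
    pairs = set()
    for rc in res:
        sites = []
        if rc.one_letter == "K" and rc.get("NZ") is not None:
            sites.append(rc.coord("NZ"))
        if rc.one_letter == "R":
            pts = [rc.coord(n) for n in ("CZ", "NE", "NH1", "NH2")]
            if all(p is not None for p in pts):
                sites.append([sum(p[k] for p in pts) / 4 for k in range(3)])
        for ra in res:
            if ra.key == rc.key or ra.one_letter not in "FYW":
                continue
            for p in sites:
                for c in _centroids(ra):
                    if _dist(p, c) <= cutoff:
                        pairs.add(_pair_key(rc, ra))
    return pairs


def brute_pi_sulfur(s, cutoff=5.3):
    res = _residues(s)
    pairs = set()
    for rs in res:
        for name in SULFUR_ATOMS.get(rs.one_letter, ()):
            a = rs.get(name)
            if a is None:
                continue
            for ra in res:
                if ra.key == rs.key or ra.one_letter not in "FYW":
                    continue
                for c in _centroids(ra):
                    if _dist(a.coords, c) <= cutoff:
                        pairs.add(_pair_key(rs, ra))
    return pairs


def brute_disulfides(s, cutoff=2.3):
    res = [r for r in _residues(s) if r.one_letter == "C"]
    pairs = set()
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            a, b = res[i].get("SG"), res[j].get("SG")
            if a is not None and b is not None and \
                    _dist(a.coords, b.coords) <= cutoff:
                pairs.add(_pair_key(res[i], res[j]))
    return pairs


BRUTE = {
    "hydrophobic": brute_hydrophobic,
    "hbond": brute_hbonds,
    "salt_bridge": brute_salt_bridges,
    "pi_pi": brute_pi_pi,
    "cation_pi": brute_cation_pi,
    "pi_sulfur": brute_pi_sulfur,
    "disulfide": brute_disulfides,
}


def affine_global_align_score_and_identity(a, b, match=1.0, mismatch=0.0,
                                           gap_open=-10.0, gap_extend=-0.5):
    """Exhaustive affine-gap global alignment by recursion with memoization.

    Returns (best_score, identity_percent) where identity is computed on the
    best-scoring alignment (identical pairs / columns excluding terminal
    overhangs). Only usable for tiny sequences.
    """
    import functools
    import sys
    sys.setrecursionlimit(10000)

    best = {"score": -math.inf, "aln": None}

    def enumerate_alignments(i, j, cols, score):
        # crude branch-and-bound free enumeration; fine for len <= 6
        if i == len(a) and j == len(b):
            if score > best["score"]:
                best["score"] = score
                best["aln"] = list(cols)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            enumerate_alignments(i + 1, j + 1, cols + [(a[i], b[j])], score + s)
        if i < len(a):
            prev_gap = cols and cols[-1][1] == "-"
            g = gap_extend if prev_gap else gap_open
            enumerate_alignments(i + 1, j, cols + [(a[i], "-")], score + g)
        if j < len(b):
            prev_gap = cols and cols[-1][0] == "-"
            g = gap_extend if prev_gap else gap_open
            enumerate_alignments(i, j + 1, cols + [("-", b[j])], score + g)

    enumerate_alignments(0, 0, [], 0.0)
    aln = best["aln"]
    lead = 0
    while lead < len(aln) and "-" in aln[lead]:
        lead += 1
    trail = len(aln)
    while trail > lead and "-" in aln[trail - 1]:
        trail -= 1
    cols = aln[lead:trail]
    if not cols:
        return best["score"], 0.0
    ident = sum(1 for x, y in cols if x == y and x != "-")
    return best["score"], 100.0 * ident / len(cols)


def kendall_tau_b_pairs(x, y):
    """Exhaustive pair-count Kendall tau-b."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom else float("nan")


def gromos_reference(M, cutoff):
    """Hand-executed greedy clustering on a precomputed RMSD matrix."""
    n = len(M)
    remaining = set(range(n))
    assignments = [-1] * n
    centers = []
    cid = 0
    while remaining:
        best_center, best_neigh = None, None
        for i in sorted(remaining):
            neigh = {j for j in remaining if M[i][j] <= cutoff}
            if best_neigh is None or len(neigh) > len(best_neigh):
                best_center, best_neigh = i, neigh
        for j in best_neigh:
            assignments[j] = cid
        centers.append(best_center)
        remaining -= best_neigh
        cid += 1
    return assignments, centers
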