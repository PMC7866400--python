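"""Geometric detection of the seven noncovalent interaction classes.

All criteria are heavy-atom distance rules (the conventions of the PIC-style
interaction census): hydrophobic side-chain contacts within 5 Å, H-bonds by
donor–acceptor distance (3.5 Å for O/N, 4.0 Å when sulfur is involved), salt
bridges within 4 Å, π–π by ring-centroid separation in 4.5–7.0 Å, cation–π
within 6 Å, π–sulfur within 5.3 Å, and disulfides at SG–SG ≤ 2.3 Å.

Each detected pair is recorded once (unordered), with its defining distance,
burial class of the pair (both-buried / both-exposed / mixed) and subunit
topology (intra- vs inter-chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    APOLAR_CONTACT, HBOND_SIDECHAIN_DONORS, HBOND_SIDECHAIN_ACCEPTORS,
    ACIDIC_O_ATOMS, BASIC_N_ATOMS, AROMATIC_RINGS, SULFUR_ATOMS,
)
from .structure_io import Structure, Residue
from .surface_burial import BurialClassification

KINDS = ("hydrophobic", "hbond", "salt_bridge", "pi_pi",
         "cation_pi", "pi_sulfur", "disulfide")


@dataclass
class CutoffConfig:
    """Distance criteria, Å."""
    hydrophobic: float = 5.0
    hbond_ON: float = 3.5
    hbond_S: float = 4.0
    salt_bridge: float = 4.0
    pi_pi_min: float = 4.5
    pi_pi_max: float = 7.0
    pi_sulfur: float = 5.3
    cation_pi: float = 6.0
    disulfide: float = 2.3

    def __post_init__(self):
        vals = asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("all cutoffs must be positive")
        if self.pi_pi_min >= self.pi_pi_max:
            raise ValueError("pi_pi_min must be below pi_pi_max")


@dataclass
class Interaction:
    kind: str
    residue_a: Residue
    residue_b: Residue
    distance: float
    burial: str | None = None     # both-buried | both-exposed | mixed
    topology: str | None = None   # intra-subunit | inter-subunit
    partner_detail: str | None = None

    @property
    def pair_key(self) -> tuple:
        return tuple(sorted([self.residue_a.key, self.residue_b.key]))


def _finalize(kind, ra, rb, dist, detail=None) -> Interaction:
    topo = "intra-subunit" if ra.chain_id == rb.chain_id else "inter-subunit"
    return Interaction(kind, ra, rb, float(dist), topology=topo,
                       partner_detail=detail)


def _dedupe_min(cands: list[Interaction]) -> list[Interaction]:
    """One record per unordered residue pair, keeping the shortest distance."""
    best: dict[tuple, Interaction] = {}
    for it in cands:
        k = it.pair_key
        if k not in best or it.distance < best[k].distance:
            best[k] = it
    return [best[k] for k in sorted(best)]


def _atom_coords(res: Residue, names) -> np.ndarray:
    pts = [res.coord(n) for n in names]
    pts = [p for p in pts if p is not None]
    return np.array(pts) if pts else np.empty((0, 3))


def _min_dist(A: np.ndarray, B: np.ndarray) -> float:
    if len(A) == 0 or len(B) == 0:
        return np.inf
    return float(cdist(A, B).min())


def _sequence_adjacent(ra: Residue, rb: Residue) -> bool:
    return ra.chain_id == rb.chain_id and abs(ra.seq_num - rb.seq_num) <= 1


def detect_hydrophobic(s: Structure, cfg: CutoffConfig = CutoffConfig()) -> list[Interaction]:
    """Apolar side-chain contacts within cfg.hydrophobic Å.

    Sequence-adjacent pairs (|Δseq| ≤ 1, same chain) are excluded.
    """
    apolar = [r for r in s.iter_residues() if r.one_letter in APOLAR_CONTACT]
    coords = [np.array([a.coords for a in r.sidechain_atoms()])
              if r.sidechain_atoms() else np.empty((0, 3)) for r in apolar]
    out = []
    for i in range(len(apolar)):
        for j in range(i + 1, len(apolar)):
            if _sequence_adjacent(apolar[i], apolar[j]):
                continue
            d = _min_dist(coords[i], coords[j])
            if d <= cfg.hydrophobic:
                out.append(_finalize("hydrophobic", apolar[i], apolar[j], d))
    return _dedupe_min(out)


def _hbond_sites(res: Residue):
    """(donor_atoms, acceptor_atoms) as lists of (name, coords, is_sulfur)."""
    donors, acceptors = [], []
    one = res.one_letter
    n = res.coord("N")
    if n is not None and one != "P":
        donors.append(("N", n, False))
    for name in ("O", "OXT"):
        o = res.coord(name)
        if o is not None:
            acceptors.append((name, o, False))
    for name in HBOND_SIDECHAIN_DONORS.get(one, ()):
        p = res.coord(name)
        if p is not None:
            donors.append((name, p, name.startswith("S")))
    for name in HBOND_SIDECHAIN_ACCEPTORS.get(one, ()):
        p = res.coord(name)
        if p is not None:
            acceptors.append((name, p, name.startswith("S")))
    return donors, acceptors


def detect_hbonds(s: Structure, cfg: CutoffConfig = CutoffConfig()) -> list[Interaction]:
    """Heavy-atom donor–acceptor pairs within the O/N (3.5 Å) or S (4.0 Å) rule.

    Main-chain-to-main-chain pairs of sequence-adjacent residues are skipped
    (those contacts are covalently forced); helical i,i+3/i+4 pairs remain.
    """
    residues = list(s.iter_residues())
    sites = [_hbond_sites(r) for r in residues]
    out = []
    for i in range(len(residues)):
        for j in range(len(residues)):
            if i == j:
                continue
            ri, rj = residues[i], residues[j]
            adjacent = _sequence_adjacent(ri, rj)
            best = None
            for dn, dxyz, ds in sites[i][0]:
                for an, axyz, asf in sites[j][1]:
                    if adjacent and dn == "N" and an in ("O", "OXT"):
                        continue
                    cutoff = cfg.hbond_S if (ds or asf) else cfg.hbond_ON
                    d = float(np.linalg.norm(dxyz - axyz))
                    if d <= cutoff and (best is None or d < best[0]):
                        mc = "main" if dn == "N" else "side"
                        ma = "main" if an in ("O", "OXT") else "side"
                        best = (d, f"{mc}-{ma}")
            if best is not None:
                # donor listed first; dedupe below keeps one record per pair
                out.append(_finalize("hbond", ri, rj, best[0], best[1]))
    return _dedupe_min(out)


def detect_salt_bridges(s: Structure, cfg: CutoffConfig = CutoffConfig()) -> list[Interaction]:
    """Carboxylate-O to basic-N contacts within cfg.salt_bridge Å.

    The C-terminal OXT counts as an acidic oxygen. partner_detail records
    the basic partner (K/R/H).
    """
    residues = list(s.iter_residues())
    acidic, basic = [], []
    for idx, r in enumerate(residues):
        one = r.one_letter
        names = list(ACIDIC_O_ATOMS.get(one, ()))
        if r.coord("OXT") is not None:
            names.append("OXT")
        pts = _atom_coords(r, names)
        if len(pts):
            acidic.append((r, pts))
        if one in BASIC_N_ATOMS:
            pts = _atom_coords(r, BASIC_N_ATOMS[one])
            if len(pts):
                basic.append((r, pts))
    out = []
    for ra, pa in acidic:
        for rb, pb in basic:
            if ra.key == rb.key:
                continue
            d = _min_dist(pa, pb)
            if d <= cfg.salt_bridge:
                out.append(_finalize("salt_bridge", ra, rb, d, rb.one_letter))
    return _dedupe_min(out)


def ring_centroids(res: Residue) -> list[np.ndarray]:
    """Aromatic ring centroid(s) of a residue; incomplete rings are skipped."""
    rings = AROMATIC_RINGS.get(res.one_letter, ())
    out = []
    for ring in rings:
        pts = _atom_coords(res, ring)
        if len(pts) == len(ring):
            out.append(pts.mean(axis=0))
        elif len(pts):
            warnings.warn(
                f"incomplete aromatic ring in {res.res_name} "
                f"{res.chain_id}{res.seq_num}; ring skipped")
    return out


def detect_pi_pi(s: Structure, cfg: CutoffConfig = CutoffConfig(),
                 exclude_pairs: set | None = None) -> list[Interaction]:
    """Ring-centroid pairs within the [pi_pi_min, pi_pi_max] window.

    Trp contributes both rings; a residue pair is counted once at its
    shortest qualifying centroid distance. Pairs in `exclude_pairs` (e.g.
    already claimed as salt bridges involving His) are suppressed.
    """
    arom = [(r, ring_centroids(r)) for r in s.iter_residues()
            if r.one_letter in AROMATIC_RINGS]
    arom = [(r, c) for r, c in arom if c]
    out = []
    for i in range(len(arom)):
        for j in range(i + 1, len(arom)):
            ra, ca = arom[i]
            rb, cb = arom[j]
            if exclude_pairs and tuple(sorted([ra.key, rb.key])) in exclude_pairs:
                continue
            dists = [float(np.linalg.norm(x - y)) for x in ca for y in cb]
            ok = [d for d in dists if cfg.pi_pi_min <= d <= cfg.pi_pi_max]
            if ok:
                out.append(_finalize("pi_pi", ra, rb, min(ok)))
    return _dedupe_min(out)


def _cation_sites(res: Residue) -> list[np.ndarray]:
    one = res.one_letter
    if one == "K":
        p = res.coord("NZ")
        return [p] if p is not None else []
    if one == "R":
        pts = _atom_coords(res, ("CZ", "NE", "NH1", "NH2"))
        return [pts.mean(axis=0)] if len(pts) == 4 else []
    return []


def detect_cation_pi(s: Structure, cfg: CutoffConfig = CutoffConfig()) -> list[Interaction]:
    """Cation (Lys NZ / Arg guanidinium midpoint) to F/Y/W ring centroid ≤ 6 Å.

    Purely geometric criterion; no electrostatic-energy filter.
    """
    cations = [(r, _cation_sites(r)) for r in s.iter_residues()
               if r.one_letter in ("K", "R")]
    cations = [(r, p) for r, p in cations if p]
    arom = [(r, ring_centroids(r)) for r in s.iter_residues()
            if r.one_letter in ("F", "Y", "W")]
    arom = [(r, c) for r, c in arom if c]
    out = []
    for rc, pc in cations:
        for ra, ca in arom:
            if rc.key == ra.key:
                continue
            dists = [float(np.linalg.norm(x - y)) for x in pc for y in ca]
            ok = [d for d in dists if d <= cfg.cation_pi]
            if ok:
                out.append(_finalize("cation_pi", rc, ra, min(ok), rc.one_letter))
    return _dedupe_min(out)


def detect_pi_sulfur(s: Structure, cfg: CutoffConfig = CutoffConfig()) -> list[Interaction]:
    """Cys SG / Met SD to F/Y/W ring centroid within cfg.pi_sulfur Å."""
    sulfurs = []
    for r in s.iter_residues():
        for name in SULFUR_ATOMS.get(r.one_letter, ()):
            p = r.coord(name)
            if p is not None:
                sulfurs.append((r, p))
    arom = [(r, ring_centroids(r)) for r in s.iter_residues()
            if r.one_letter in ("F", "Y", "W")]
    arom = [(r, c) for r, c in arom if c]
    out = []
    for rs, ps in sulfurs:
        for ra, ca in arom:
            if rs.key == ra.key:
                continue
            ok = [float(np.linalg.norm(ps - y)) for y in ca]
            ok = [d for d in ok if d <= cfg.pi_sulfur]
            if ok:
                out.append(_finalize("pi_sulfur", rs, ra, min(ok)))
    return _dedupe_min(out)


def detect_disulfides(s: Structure, cfg: CutoffConfig = CutoffConfig()) -> list[Interaction]:
    """Cys SG–SG pairs within cfg.disulfide Å."""
    cys = [(r, r.coord("SG")) for r in s.iter_residues() if r.one_letter == "C"]
    cys = [(r, p) for r, p in cys if p is not None]
    out = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1] - cys[j][1]))
            if d <= cfg.disulfide:
                out.append(_finalize("disulfide", cys[i][0], cys[j][0], d))
    return _dedupe_min(out)


_DETECTORS = {
    "hydrophobic": detect_hydrophobic,
    "hbond": detect_hbonds,
    "salt_bridge": detect_salt_bridges,
    "pi_pi": detect_pi_pi,
    "cation_pi": detect_cation_pi,
    "pi_sulfur": detect_pi_sulfur,
    "disulfide": detect_disulfides,
}


def detect_all(s: Structure, cfg: CutoffConfig = CutoffConfig(),
               burial: BurialClassification | None = None) -> dict[str, list[Interaction]]:
    """Run every detector with His precedence (salt bridge over π–π) and
    optional burial annotation."""
    out: dict[str, list[Interaction]] = {}
    out["salt_bridge"] = detect_salt_bridges(s, cfg)
    sb_pairs = {it.pair_key for it in out["salt_bridge"]}
    out["hydrophobic"] = detect_hydrophobic(s, cfg)
    out["hbond"] = detect_hbonds(s, cfg)
    out["pi_pi"] = detect_pi_pi(s, cfg, exclude_pairs=sb_pairs)
    out["cation_pi"] = detect_cation_pi(s, cfg)
    out["pi_sulfur"] = detect_pi_sulfur(s, cfg)
    out["disulfide"] = detect_disulfides(s, cfg)
    if burial is not None:
        for items in out.values():
            annotate_burial(items, burial)
    return {k: out[k] for k in KINDS}


def annotate_burial(interactions: list[Interaction],
                    burial: BurialClassification) -> None:
    for it in interactions:
        a = burial.labels[it.residue_a.key]
        b = burial.labels[it.residue_b.key]
        if a == b == "buried":
            it.burial = "both-buried"
        elif a == b == "exposed":
            it.burial = "both-exposed"
        else:
            it.burial = "mixed"


@dataclass
class InteractionSummary:
    n_residues: int
    counts: dict[str, int] = field(default_factory=dict)
    per_100: dict[str, float] = field(default_factory=dict)
    burial_split: dict[str, dict[str, int]] = field(default_factory=dict)
    inter_subunit: dict[str, int] = field(default_factory=dict)
    salt_bridge_partners: dict[str, int] = field(default_factory=dict)


def summarize(interactions: dict[str, list[Interaction]], s: Structure,
              burial: BurialClassification | None = None,
              n_residues: int | None = None) -> InteractionSummary:
    """Raw and per-100-residue counts with burial/topology/partner splits.

    `n_residues` overrides the per-100 denominator (e.g. to normalize a
    dimer census by the monomer residue count).
    """
    n = n_residues if n_residues is not None else s.n_residues
    summ = InteractionSummary(n_residues=n)
    for kind in KINDS:
        items = interactions.get(kind, [])
        if burial is not None:
            annotate_burial(items, burial)
        summ.counts[kind] = len(items)
        summ.per_100[kind] = 100.0 * len(items) / n if n else 0.0
        summ.inter_subunit[kind] = sum(
            1 for it in items if it.topology == "inter-subunit")
        split = {"both-buried": 0, "both-exposed": 0, "mixed": 0, "unknown": 0}
        for it in items:
            split[it.burial or "unknown"] += 1
        summ.burial_split[kind] = split
    summ.salt_bridge_partners = {p: 0 for p in "KRH"}
    for it in interactions.get("salt_bridge", []):
        if it.partner_detail in summ.salt_bridge_partners:
            summ.salt_bridge_partners[it.partner_detail] += 1
    return summ
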