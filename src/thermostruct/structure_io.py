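"""PDB-format structure model, parsing, selection, and writing.

The coordinate model is a small hierarchy (Structure -> Chain -> Residue ->
Atom) tuned for the distance-geometry detectors in this package rather than
full mmCIF generality. Parsing keeps protein heavy atoms only: hydrogens,
waters, and non-MSE heteroatoms are dropped, alternate locations are resolved
to the highest-occupancy conformer (ties to the lexicographically first
altLoc), and MSE is treated as methionine.

Sequence identity between homologs is computed from a global alignment
(match +1, mismatch 0, gap open -10, gap extend -0.5) as identical pairs over
alignment columns, excluding terminal gap overhangs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import Align

from .constants import THREE_TO_ONE, ONE_TO_THREE

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBFormatError(ValueError):
    """Raised for unparseable or empty PDB input."""


class NotFoundError(KeyError):
    """Raised when a requested model, chain, or residue is absent."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    coords: np.ndarray
    occupancy: float = 1.0
    residue_key: tuple | None = None  # (chain_id, seq_num, insertion_code)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    def coord(self, atom_name: str) -> np.ndarray | None:
        a = self.get(atom_name)
        return None if a is None else a.coords

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.element != "H"])

    def sidechain_atoms(self) -> list[Atom]:
        mainchain = {"N", "CA", "C", "O", "OXT"}
        return [a for a in self.atoms if a.name not in mainchain and a.element != "H"]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise NotFoundError(f"chain {chain_id!r} not in structure {self.id!r}")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.chain_id == chain_id for c in self.chains)

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[Atom]:
        for r in self.iter_residues():
            yield from r.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def coords(self) -> np.ndarray:
        """All atom coordinates in hierarchy order, (n_atoms, 3) Å."""
        out = np.empty((self.n_atoms, 3))
        for i, a in enumerate(self.iter_atoms()):
            out[i] = a.coords
        return out

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for i, a in enumerate(self.iter_atoms()):
            a.coords = xyz[i].copy()

    def copy(self) -> "Structure":
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    Atom(a.serial, a.name, a.element, a.alt_loc,
                         a.coords.copy(), a.occupancy, a.residue_key)
                    for a in r.atoms
                ]
                residues.append(Residue(r.chain_id, r.seq_num, r.insertion_code,
                                        r.res_name, atoms))
            chains.append(Chain(c.chain_id, residues))
        return Structure(self.id, chains, self.model_index)


def _infer_element(atom_name: str) -> str:
    raw = atom_name.strip()
    for ch in raw:
        if ch.isalpha():
            # two-letter elements appearing in protein PDB files
            if raw[:2].upper() in ("SE", "CL", "BR", "FE", "ZN", "MG", "NA"):
                return raw[:2].upper()
            return ch.upper()
    return ""


def _parse_atom_record(line: str) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        seq_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record: {line.rstrip()!r}") from exc
    if not element:
        element = _infer_element(name)
    return serial, name, alt_loc, res_name, chain_id, seq_num, icode, (x, y, z), occupancy, element


def parse_pdb(text: str | Iterable[str], model: int | None = None,
              structure_id: str = "structure", keep_hetero: bool = False) -> Structure:
    """Parse a PDB-format character stream into a Structure.

    One model is read (`model` is the 1-based MODEL serial; default: first
    encountered). Waters and ligands are dropped; MSE is kept as MET.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = list(text)

    current_model = None
    seen_models: list[int] = []
    # records[(chain, seq, icode)] -> residue bucket
    order: list[tuple] = []
    buckets: dict[tuple, dict] = {}
    in_wanted_model = model is None

    n_atom_records = 0
    for line in lines:
        rec = line[:6]
        if rec == "MODEL ":
            try:
                current_model = int(line[10:14])
            except ValueError:
                current_model = (seen_models[-1] + 1) if seen_models else 1
            seen_models.append(current_model)
            if model is None:
                in_wanted_model = len(seen_models) == 1
            else:
                in_wanted_model = current_model == model
            continue
        if rec == "ENDMDL":
            in_wanted_model = model is None and not seen_models
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        n_atom_records += 1
        if not in_wanted_model:
            continue
        (serial, name, alt_loc, res_name, chain_id, seq_num, icode,
         xyz, occ, element) = _parse_atom_record(line)
        if element in ("H", "D"):
            continue
        if rec == "HETATM":
            if res_name in _WATER_NAMES:
                continue
            if res_name == "MSE":
                res_name = "MET"
                if name == "SE":
                    name, element = "SD", "S"
            elif not keep_hetero:
                continue
        elif res_name == "MSE":
            res_name = "MET"
            if name == "SE":
                name, element = "SD", "S"
        key = (chain_id, seq_num, icode)
        if key not in buckets:
            buckets[key] = {"res_name": res_name, "atoms": {}}
            order.append(key)
        bucket = buckets[key]["atoms"]
        # altLoc resolution: keep highest occupancy, ties -> lexicographic altLoc
        prev = bucket.get(name)
        if prev is None or occ > prev[0] or (occ == prev[0] and alt_loc < prev[1]):
            bucket[name] = (occ, alt_loc, serial, element, xyz)

    if n_atom_records == 0:
        raise PDBFormatError("no ATOM/HETATM records in input")
    if model is not None and (seen_models and model not in seen_models):
        raise NotFoundError(f"model {model} not present (models: {seen_models})")
    if not order:
        raise PDBFormatError("no protein atoms retained from input")

    chains: list[Chain] = []
    chain_map: dict[str, Chain] = {}
    for key in order:
        chain_id, seq_num, icode = key
        info = buckets[key]
        atoms = []
        for name, (occ, alt, serial, element, xyz) in info["atoms"].items():
            atoms.append(Atom(serial, name, element, alt, np.array(xyz), occ, key))
        res = Residue(chain_id, seq_num, icode, info["res_name"], atoms)
        if chain_id not in chain_map:
            chain_map[chain_id] = Chain(chain_id)
            chains.append(chain_map[chain_id])
        chain_map[chain_id].residues.append(res)
    return Structure(structure_id, chains)


def write_pdb(s: Structure, end: bool = True) -> str:
    """Serialize a Structure to PDB format (ATOM/TER records)."""
    lines = []
    serial = 0
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4.4s}{'':1s}{res.res_name:>3s} "
                    f"{chain.chain_id:1s}{res.seq_num:4d}{res.insertion_code:>1s}"
                    f"   {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    if end:
        lines.append("END")
    return "\n".join(lines) + "\n"


def _resolve_residue_index(chain: Chain, spec) -> int:
    """Residue spec: int seq_num, 'G23'-style code+number, or (seq, icode)."""
    icode = ""
    expected_aa = None
    if isinstance(spec, tuple):
        seq_num, icode = spec
    elif isinstance(spec, str) and spec and spec[0].isalpha():
        expected_aa = spec[0].upper()
        seq_num = int(spec[1:])
    else:
        seq_num = int(spec)
    for i, r in enumerate(chain.residues):
        if r.seq_num == seq_num and (not icode or r.insertion_code == icode):
            if expected_aa and r.one_letter != expected_aa:
                raise NotFoundError(
                    f"residue {seq_num} is {r.one_letter}, expected {expected_aa}")
            return i
    raise NotFoundError(f"residue {spec!r} not in chain {chain.chain_id}")


def select_domain(s: Structure, chain: str, start, end) -> Structure:
    """Restrict to residues [start, end] (inclusive, chain order) of one chain.

    start/end accept PDB author numbers or 'G23'-style residue codes.
    """
    c = s.chain(chain)
    i0 = _resolve_residue_index(c, start)
    i1 = _resolve_residue_index(c, end)
    if i0 > i1:
        raise ValueError("start residue comes after end residue in chain order")
    out = s.copy()
    kept = out.chain(chain).residues[i0:i1 + 1]
    out.chains = [Chain(chain, kept)]
    out.id = f"{s.id}:{chain}"
    return out


def extract_sequence(s: Structure, chain: str) -> str:
    """One-letter sequence of a chain in residue order; unknowns become 'X'."""
    return "".join(r.one_letter for r in s.chain(chain))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment.

    Identity = identical aligned pairs / alignment columns, where columns
    inside terminal gap overhangs (leading/trailing columns gapped in either
    sequence) are excluded from the denominator.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    ga, gb = alignment[0], alignment[1]
    n = len(ga)
    lead = 0
    while lead < n and (ga[lead] == "-" or gb[lead] == "-"):
        lead += 1
    trail = n
    while trail > lead and (ga[trail - 1] == "-" or gb[trail - 1] == "-"):
        trail -= 1
    cols = trail - lead
    if cols == 0:
        return 0.0
    ident = sum(1 for i in range(lead, trail) if ga[i] == gb[i] and ga[i] != "-")
    return 100.0 * ident / cols


def one_to_three(letter: str) -> str:
    try:
        return ONE_TO_THREE[letter.upper()]
    except KeyError:
        raise ValueError(f"no 3-letter code for {letter!r}")
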