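"""Sequence-level compositional features.

Covers the residue-class fractions (charged DEHKR / hydrophobic GAVLIPMFW /
uncharged polar CNQSTY), the acid/base (D+E)/(K+R) and Arg/Lys ratios, and
the isoelectric point under the Bjellqvist pKa set (the ProtParam
convention), solved by bisection on the monotone net-charge curve.

'X' residues are counted in n_residues but excluded from class tallies and
from the charge model.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .constants import (
    CLASS_CHARGED, CLASS_HYDROPHOBIC, CLASS_POLAR, STANDARD_AA,
    PKA_SIDECHAIN_NEG, PKA_SIDECHAIN_POS, PKA_CTERM,
    PKA_NTERM, PKA_NTERM_DEFAULT,
)


@dataclass
class CompositionProfile:
    counts: dict[str, int]
    n_residues: int
    charged_fraction: float      # percent
    hydrophobic_fraction: float  # percent
    polar_fraction: float        # percent
    acidic_basic_ratio: float    # (D+E)/(K+R)
    rk_ratio: float              # R/K
    pI: float
    ratio_overflow: bool = False  # True when a zero denominator gave +inf

    def count(self, aa: str) -> int:
        return self.counts.get(aa.upper(), 0)


def net_charge(seq: str, pH: float) -> float:
    """Net protein charge at a given pH under the Bjellqvist pKa set."""
    seq = _clean(seq)
    counts = Counter(seq)
    pos = 0.0
    neg = 0.0
    # termini (charge only on standard first/last residues)
    first = seq[0] if seq else ""
    if first in STANDARD_AA:
        pka_n = PKA_NTERM.get(first, PKA_NTERM_DEFAULT)
        pos += 1.0 / (1.0 + 10 ** (pH - pka_n))
    last = seq[-1] if seq else ""
    if last in STANDARD_AA:
        neg += 1.0 / (1.0 + 10 ** (PKA_CTERM - pH))
    for aa, pka in PKA_SIDECHAIN_POS.items():
        pos += counts.get(aa, 0) / (1.0 + 10 ** (pH - pka))
    for aa, pka in PKA_SIDECHAIN_NEG.items():
        neg += counts.get(aa, 0) / (1.0 + 10 ** (pka - pH))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge curve is strictly decreasing in pH, so the root is unique.
    """
    seq = _clean(seq)
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    # charge(0) > 0 > charge(14) holds for any peptide with termini
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _clean(seq: str) -> str:
    seq = "".join(seq.split()).upper()
    bad = set(seq) - STANDARD_AA - {"X"}
    if bad:
        raise ValueError(f"unknown residue codes: {sorted(bad)}")
    return seq


def composition_profile(seq: str) -> CompositionProfile:
    """Full compositional profile of a one-letter sequence."""
    seq = _clean(seq)
    if not seq:
        raise ValueError("empty sequence")
    counts = dict(Counter(seq))
    known = sum(v for k, v in counts.items() if k != "X")
    def frac(cls):
        if known == 0:
            return 0.0
        return 100.0 * sum(counts.get(a, 0) for a in cls) / known
    d_e = counts.get("D", 0) + counts.get("E", 0)
    k_r = counts.get("K", 0) + counts.get("R", 0)
    overflow = False
    if k_r:
        ab_ratio = d_e / k_r
    else:
        ab_ratio, overflow = math.inf, True
    if counts.get("K", 0):
        rk = counts.get("R", 0) / counts["K"]
    else:
        rk, overflow = math.inf, True
    return CompositionProfile(
        counts=counts,
        n_residues=len(seq),
        charged_fraction=frac(CLASS_CHARGED),
        hydrophobic_fraction=frac(CLASS_HYDROPHOBIC),
        polar_fraction=frac(CLASS_POLAR),
        acidic_basic_ratio=ab_ratio,
        rk_ratio=rk,
        pI=isoelectric_point(seq),
        ratio_overflow=overflow,
    )
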