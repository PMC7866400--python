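import numpy as np
import pytest

from thermostruct import interactions as ints
from thermostruct import synthetic_data as synth
from thermostruct.structure_io import Structure, Chain
from thermostruct.surface_burial import BurialClassification

import oracles
from conftest import random_rotation

CFG = ints.CutoffConfig()

DETECTORS = {
    "hydrophobic": ints.detect_hydrophobic,
    "hbond": ints.detect_hbonds,
    "salt_bridge": ints.detect_salt_bridges,
    "pi_pi": ints.detect_pi_pi,
    "cation_pi": ints.detect_cation_pi,
    "pi_sulfur": ints.detect_pi_sulfur,
    "disulfide": ints.detect_disulfides,
}
PLANT_TO_DETECTOR = {"hbond_s": "hbond"}


def pair_set(items):
    return {it.pair_key for it in items}


def merged_random_fixture(rng, kinds, n=4):
    """Several planted fixtures merged into one structure at spread offsets."""
    chains = []
    seq0 = 1
    for k in range(n):
        kind = kinds[rng.integers(len(kinds))]
        lo, hi = 1.8, 8.5
        if kind == "disulfide":
            lo, hi = 1.9, 3.0
        d = float(rng.uniform(lo, hi))
        s = synth.plant_interaction(kind, d)
        offset = np.array([0.0, 0.0, 40.0 * k])
        for chain in s.chains:
            for r in chain.residues:
                r.seq_num = seq0 + (0 if r.seq_num == 1 else 4)
                r.chain_id = "A"
                for a in r.atoms:
                    a.coords = a.coords + offset
                    a.residue_key = (r.chain_id, r.seq_num, "")
        seq0 += 10
        chains.extend(s.chains)
    residues = [r for c in chains for r in c.residues]
    return Structure("merged", [Chain("A", residues)])


class TestDetectorsAgainstBruteForce:
    @pytest.mark.parametrize("kind", list(DETECTORS))
    def test_planted_fixture_equivalence(self, kind):
        plant_kind = "hbond_s" if kind == "pi_sulfur" else kind
        for d in (2.0, 3.0, 4.2, 5.2, 6.5):
            if kind == "disulfide" and d > 3.0:
                continue
            s = synth.plant_interaction(kind if kind != "hbond" else "hbond", d)
            assert pair_set(DETECTORS[kind](s, CFG)) == oracles.BRUTE[kind](s)

    def test_merged_random_fixtures_equivalence(self, rng):
        kinds = list(synth.PLANT_KINDS)
        for trial in range(15):
            s = merged_random_fixture(rng, kinds)
            for kind, fn in DETECTORS.items():
                assert pair_set(fn(s, CFG)) == oracles.BRUTE[kind](s), kind

    def test_homolog_structure_equivalence(self, homolog_pair):
        s = homolog_pair["floppy"]["structure"]
        for kind, fn in DETECTORS.items():
            assert pair_set(fn(s, CFG)) == oracles.BRUTE[kind](s), kind


class TestDetectorProperties:
    def test_rigid_motion_and_order_invariance(self, rng):
        s = merged_random_fixture(rng, list(synth.PLANT_KINDS))
        before = {k: pair_set(fn(s, CFG)) for k, fn in DETECTORS.items()}
        R = random_rotation(rng)
        t = np.array([7.0, -13.0, 2.0])
        s.set_coords(s.coords() @ R.T + t)
        s.chains[0].residues = s.chains[0].residues[::-1]
        after = {k: pair_set(fn(s, CFG)) for k, fn in DETECTORS.items()}
        assert before == after

    def test_counts_monotone_in_cutoff(self, rng):
        s = merged_random_fixture(rng, ["hydrophobic", "salt_bridge"])
        counts = []
        for c in np.linspace(3.0, 8.0, 11):
            cfg = ints.CutoffConfig(hydrophobic=c, salt_bridge=c)
            counts.append((len(ints.detect_hydrophobic(s, cfg)),
                           len(ints.detect_salt_bridges(s, cfg))))
        assert all(a[0] <= b[0] and a[1] <= b[1]
                   for a, b in zip(counts, counts[1:]))

    def test_pi_pi_monotone_in_window_width(self):
        s = synth.plant_interaction("pi_pi", 5.5)
        narrow = ints.detect_pi_pi(s, ints.CutoffConfig(pi_pi_min=5.6, pi_pi_max=5.8))
        wide = ints.detect_pi_pi(s, ints.CutoffConfig(pi_pi_min=4.5, pi_pi_max=7.0))
        assert len(narrow) <= len(wide)
        assert len(wide) == 1

    def test_sequence_adjacent_hydrophobic_excluded(self):
        s = synth.plant_interaction("hydrophobic", 4.0)
        for r in s.iter_residues():
            if r.seq_num == 5:
                r.seq_num = 2
                for a in r.atoms:
                    a.residue_key = ("A", 2, "")
        assert ints.detect_hydrophobic(s, CFG) == []

    def test_sulfur_rule_extends_hbond_cutoff(self):
        s = synth.plant_interaction("hbond_s", 3.8)
        found = ints.detect_hbonds(s, CFG)
        assert len(found) == 1
        s2 = synth.plant_interaction("hbond", 3.8)  # O...O pair beyond 3.5
        assert ints.detect_hbonds(s2, CFG) == []

    def test_salt_bridge_partner_detail(self):
        s = synth.plant_interaction("salt_bridge", 3.9)
        found = ints.detect_salt_bridges(s, CFG)
        assert found[0].partner_detail == "K"

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            ints.CutoffConfig(hydrophobic=-1.0)
        with pytest.raises(ValueError):
            ints.CutoffConfig(pi_pi_min=7.0, pi_pi_max=4.5)


class TestSummarize:
    def test_per_100_arithmetic(self):
        s = synth.plant_interaction("salt_bridge", 3.9)
        detected = {"salt_bridge": ints.detect_salt_bridges(s, CFG)}
        summary = ints.summarize(detected, s, n_residues=311)
        # 13 bridges over 311 residues would give 4.18; here 1 bridge
        assert summary.per_100["salt_bridge"] == pytest.approx(100.0 / 311, rel=1e-9)
        assert 13 * summary.per_100["salt_bridge"] == pytest.approx(4.18, abs=0.005)

    def test_splits_sum_to_totals(self, rng, homolog_pair):
        from thermostruct import surface_burial as sb
        s = homolog_pair["stable"]["structure"]
        sasa = sb.shrake_rupley(s, n_points=240)
        burial = sb.classify_burial(s, sasa, threshold=0.25)
        detected = ints.detect_all(s, CFG, burial=burial)
        summary = ints.summarize(detected, s)
        for kind in ints.KINDS:
            split = summary.burial_split[kind]
            assert sum(split.values()) == summary.counts[kind]
            assert split["unknown"] == 0

    def test_single_chain_has_no_inter_subunit(self, homolog_pair):
        s = homolog_pair["stable"]["structure"]
        summary = ints.summarize(ints.detect_all(s, CFG), s)
        assert all(v == 0 for v in summary.inter_subunit.values())

    def test_his_pair_claimed_by_salt_bridge_not_pi_pi(self):
        # planted His ring near an Asp carboxylate: qualifies as salt bridge
        from thermostruct.synthetic_data import _mini_residue, _ring_atoms
        ring = _ring_atoms((0, 0, 0), (1, 0, 0),
                           ("CG", "ND1", "CD2", "CE1", "NE2"), radius=1.17)
        his = _mini_residue("A", 1, "HIS", [("CA", "C", (-8, 0, 0))] + ring)
        asp = _mini_residue("A", 5, "ASP", [("CA", "C", (11.5, 0, 0)),
                                            ("OD1", "O", (3.5, 0, 0))])
        s = Structure("his-asp", [Chain("A", [his, asp])])
        detected = ints.detect_all(s)
        assert len(detected["salt_bridge"]) == 1
        assert detected["pi_pi"] == []
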