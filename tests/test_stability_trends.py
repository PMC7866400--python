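import numpy as np
import pandas as pd
import pytest

from thermostruct import stability_trends as st
from thermostruct import interactions as ints

import oracles


def records(tms, topts=None):
    topts = topts or tms
    return [st.StabilityRecord(f"p{i}", t_opt=o, t_m=m)
            for i, (m, o) in enumerate(zip(tms, topts))]


class TestTrendArrow:
    def test_perfect_concordance_up(self):
        vals = {"p0": 1.0, "p1": 2.0, "p2": 3.0}
        assert st.trend_arrow(vals, records([50, 60, 70])).arrow == "up"

    def test_perfect_discordance_down(self):
        vals = {"p0": 3.0, "p1": 2.0, "p2": 1.0}
        assert st.trend_arrow(vals, records([50, 60, 70])).arrow == "down"

    def test_tau_matches_pair_count_oracle(self):
        vals = {f"p{i}": v for i, v in enumerate([1.0, 3.0, 2.0, 5.0, 4.0])}
        tms = [10, 20, 30, 40, 50]
        res = st.trend_arrow(vals, records(tms))
        expected = oracles.kendall_tau_b_pairs([1, 3, 2, 5, 4], tms)
        assert res.tau == pytest.approx(expected)

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            v = rng.normal(size=5)
            vals = {f"p{i}": x for i, x in enumerate(v)}
            neg = {f"p{i}": -x for i, x in enumerate(v)}
            tms = list(rng.normal(size=5))
            a = st.trend_arrow(vals, records(tms))
            b = st.trend_arrow(neg, records(tms))
            if a.tau is not None and not np.isnan(a.tau):
                assert b.tau == pytest.approx(-a.tau)
                flip = {"up": "down", "down": "up", "none": "none"}
                assert b.arrow == flip[a.arrow]

    def test_insufficient_data(self):
        assert st.trend_arrow({"p0": 1.0, "p1": 2.0},
                              records([50, 60])).arrow == "insufficient-data"


class TestHotspotAggregate:
    def test_per_residue_sum(self):
        scores = [st.MutationScore("x", "N67", "N", "I", 1.0),
                  st.MutationScore("x", "N67", "N", "V", 2.0)]
        out = st.hotspot_aggregate(scores)
        assert out["per_residue_sums"]["N67"] == pytest.approx(3.0)

    def test_published_style_top_mutation_ranks_first(self):
        # score table shaped like an external predictor's output for the
        # cold-adapted homolog: E357I at +3.5 K is the strongest stabilizer
        rows = [("E357", "E", "I", 3.5), ("E357", "E", "V", 3.2),
                ("E357", "E", "Y", 3.2), ("A103", "A", "P", 0.7),
                ("N170", "N", "P", 0.5), ("L321", "L", "P", -9.0)]
        scores = [st.MutationScore("P-As", p, f, t, d) for p, f, t, d in rows]
        out = st.hotspot_aggregate(scores, direction="stabilizing", top_k=3)
        top = out["top_mutations"][0]
        assert (top.position, top.to_aa, top.delta_tm) == ("E357", "I", 3.5)
        assert out["top_residues"][0][0] == "E357"

    def test_catalytic_exclusion(self):
        scores = [st.MutationScore("x", "E357", "E", "I", 3.5),
                  st.MutationScore("x", "A10", "A", "P", 1.0)]
        out = st.hotspot_aggregate(scores, exclude_positions={"E357"})
        assert out["top_mutations"][0].position == "A10"

    def test_destabilizing_direction(self):
        scores = [st.MutationScore("x", "G1", "G", "P", -5.0),
                  st.MutationScore("x", "A2", "A", "P", -1.0)]
        out = st.hotspot_aggregate(scores, direction="destabilizing")
        assert out["top_mutations"][0].position == "G1"

    def test_sums_permutation_invariant_and_additive(self):
        rng = np.random.default_rng(3)
        scores = [st.MutationScore("x", f"R{i % 4}", "A", "G", float(v))
                  for i, v in enumerate(rng.normal(size=20))]
        shuffled = list(scores)
        rng.shuffle(shuffled)
        a = st.hotspot_aggregate(scores)["per_residue_sums"]
        b = st.hotspot_aggregate(shuffled)["per_residue_sums"]
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k])
        half1 = st.hotspot_aggregate(scores[:10])["per_residue_sums"]
        half2 = st.hotspot_aggregate(scores[10:])["per_residue_sums"]
        for k in a:
            assert a[k] == pytest.approx(half1.get(k, 0) + half2.get(k, 0))

    def test_region_filter(self):
        scores = [st.MutationScore("x", "A1", "A", "V", 2.0, region="L1"),
                  st.MutationScore("x", "A2", "A", "V", 9.0, region="L2")]
        out = st.hotspot_aggregate(scores, region="L1")
        assert list(out["per_residue_sums"]) == ["A1"]

    def test_self_mutation_rejected(self):
        with pytest.raises(ValueError):
            st.MutationScore("x", "A1", "A", "A", 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.hotspot_aggregate([])

    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("protein\tposition\tfrom\tto\tdelta_tm\tregion\n"
                     "P-As\tE357\tE\tI\t3.5\toverall\n")
        scores = st.read_mutation_scores(p)
        assert len(scores) == 1 and scores[0].delta_tm == 3.5


@pytest.fixture(scope="module")
def report(homolog_pair):
    structures = {k: v["structure"] for k, v in homolog_pair.items()}
    stability = [st.StabilityRecord(k, t_opt=v["t_opt"], t_m=v["t_m"],
                                    class_label=v["class"])
                 for k, v in homolog_pair.items()]
    return st.assemble_report(structures, stability, sasa_points=240)


class TestAssembleReport:

    def test_raw_and_per100_consistent(self, report):
        table = report["table"]
        for pid in table.columns:
            n = table.at["n_residues", pid]
            for kind in ints.KINDS:
                raw = table.at[f"{kind}_count", pid]
                per100 = table.at[f"{kind}_per_100", pid]
                assert per100 == pytest.approx(100.0 * raw / n)

    def test_identical_structures_identical_columns(self, homolog_pair):
        s = homolog_pair["stable"]["structure"]
        rep = st.assemble_report({"a": s, "b": s.copy()},
                                 records([50, 50]), sasa_points=240)
        pd.testing.assert_series_equal(rep["table"]["a"], rep["table"]["b"],
                                       check_names=False)

    def test_pipeline_equals_stage_by_stage(self, report, homolog_pair):
        from thermostruct import composition as comp
        from thermostruct.structure_io import extract_sequence
        s = homolog_pair["stable"]["structure"]
        seq = extract_sequence(s, "A")
        profile = comp.composition_profile(seq)
        assert report["table"].at["pI", "stable"] == pytest.approx(profile.pI)
        from thermostruct import secondary_structure as ssm
        content = ssm.ss_content(ssm.assign_ss(s))
        assert report["table"].at["helix_percent", "stable"] == \
            pytest.approx(content["helix"])

    def test_write_report_deterministic(self, report, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        p1 = st.write_report(report, d1)
        p2 = st.write_report(report, d2)
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()
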