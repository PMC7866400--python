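#!/usr/bin/env python
"""Aggregate per-mutation stability scores into hotspot rankings.

Mutation scores (predicted melting-temperature changes, Kelvin) are input
data from an external predictor; this script writes a small synthetic score
table shaped like such output, then ranks the top stabilizing and
destabilizing mutations overall and within the floppy loop, excluding the
catalytic residues. Results go to results/hotspots/.
"""

import json
from pathlib import Path

from thermostruct import stability_trends as st

OUT = Path(__file__).resolve().parent.parent / "results" / "hotspots"

# synthetic score table for the floppy homolog (delta T_m in Kelvin);
# catalytic acidic residues E27/E29 are listed but must be excluded
SCORES_TSV = """\
protein\tposition\tfrom\tto\tdelta_tm\tregion
floppy\tE15\tE\tI\t3.5\toverall
floppy\tE15\tE\tV\t3.2\toverall
floppy\tS12\tS\tP\t1.9\tL1
floppy\tG13\tG\tA\t1.4\tL1
floppy\tK18\tK\tM\t1.1\tL1
floppy\tE27\tE\tI\t4.0\toverall
floppy\tE29\tE\tV\t3.8\toverall
floppy\tL24\tL\tP\t-9.0\toverall
floppy\tI25\tI\tG\t-7.2\toverall
floppy\tG13\tG\tP\t-5.1\tL1
"""


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    scores_path = OUT / "mutation_scores.tsv"
    scores_path.write_text(SCORES_TSV)
    scores = st.read_mutation_scores(scores_path)
    catalytic = {"E27", "E29"}

    out = {}
    for direction in ("stabilizing", "destabilizing"):
        overall = st.hotspot_aggregate(scores, direction=direction,
                                       exclude_positions=catalytic)
        loop = st.hotspot_aggregate(scores, region="L1", direction=direction,
                                    exclude_positions=catalytic)
        out[direction] = {
            "overall_top": [(m.position, m.to_aa, m.delta_tm)
                            for m in overall["top_mutations"]],
            "loop_top": [(m.position, m.to_aa, m.delta_tm)
                         for m in loop["top_mutations"]],
            "residue_sums": overall["per_residue_sums"],
        }
        print(f"{direction}: top overall {out[direction]['overall_top'][0]}, "
              f"top in floppy loop {out[direction]['loop_top'][0]}")
    with open(OUT / "hotspots.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    print(f"catalytic residues excluded: {sorted(catalytic)}; "
          f"report at {OUT / 'hotspots.json'}")


if __name__ == "__main__":
    main()
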