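#!/usr/bin/env python
"""Generate the synthetic stable/floppy homolog pair and their trajectories.

Writes the structures (PDB), fluctuation trajectories (multi-model PDB),
and the planted ground truth (JSON) under results/synthetic/. These inputs
stand in for deposited X-ray structures and MD output in the downstream
analysis scripts.
"""

import json
from pathlib import Path

from thermostruct import synthetic_data as synth
from thermostruct import trajectory_analysis as ta
from thermostruct.structure_io import write_pdb

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
N_FRAMES = 200
SEED = 2021


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pair = synth.mini_homolog_pair()
    truth = {}
    for name, info in pair.items():
        s = info["structure"]
        (OUT / f"{name}.pdb").write_text(write_pdb(s))
        traj, t = synth.fluctuation_trajectory(s, info["sigma_nm"], N_FRAMES,
                                               seed=SEED)
        (OUT / f"{name}_traj.pdb").write_text(ta.write_trajectory_pdb(traj))
        truth[name] = {**t, "active_site": [list(x) for x in info["active_site"]],
                       "floppy_loop_span": list(info["floppy_loop_span"]),
                       "t_m_C": info["t_m"], "t_opt_C": info["t_opt"],
                       "class": info["class"]}
        print(f"{name}: {s.n_residues} residues, {N_FRAMES} frames "
              f"(sigma profile min/max {min(info['sigma_nm'])}/"
              f"{max(info['sigma_nm'])} nm)")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    print(f"wrote structures, trajectories and ground truth to {OUT}")


if __name__ == "__main__":
    main()
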