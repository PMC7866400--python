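# thermostruct

Comparative structural analysis of thermally adapted protein homologs.

Psychrophilic (cold-adapted), mesophilic, and thermophilic homologs of the
same enzyme — the motivating case is the GH18 chitinase family, whose
(β/α)₈ TIM-barrel holds the active site under a crown of surface loops —
differ in melting temperature (T_m) and optimal activity temperature
(T_opt) far more than in fold. `thermostruct` computes, from PDB
structures and (optionally) MD trajectory frames, the feature set used to
rationalize those differences:

- **composition**: residue-class fractions (charged DEHKR, hydrophobic
  GAVLIPMFW, uncharged polar CNQSTY), (D+E)/(K+R) and R/K ratios, and the
  isoelectric point pI under the Bjellqvist pKa set (net charge
  Z(pH) = Σ⁺ 1/(1+10^(pH−pKa)) − Σ⁻ 1/(1+10^(pKa−pH)), solved by bisection);
- **secondary structure**: a native Kabsch–Sander assignment (backbone
  H-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
  bond below −0.5) reduced to H/E/C, with loop extraction, long-loop
  counts (>10 residues), helix N-/C-cap charge census and Gly/Pro placement;
- **surface & burial**: Shrake–Rupley SASA on a deterministic golden-spiral
  lattice, relative accessibility against Gly-X-Gly reference maxima,
  buried-residue tallies, and dimer interface area
  (SASA_A + SASA_B − SASA_AB)/2;
- **interactions**: seven geometric detector classes — hydrophobic
  side-chain contacts (≤5 Å), H-bonds (donor–acceptor ≤3.5 Å, 4.0 Å with
  sulfur), salt bridges (carboxylate O to basic N ≤4 Å), π–π (centroid
  4.5–7.0 Å), cation–π (≤6 Å), π–sulfur (≤5.3 Å), disulfides (≤2.3 Å) —
  with per-100-residue normalization, buried/exposed and
  intra-/inter-subunit splits;
- **trajectory analysis**: Kabsch superposition, RMSD/RMSF/Rg/SASA series,
  and greedy ("gromos") RMSD clustering with the RMS-matrix histogram;
- **loop flexibility**: ranking of coil segments by RMSF and their
  proximity to / occlusion of the active site over a trajectory;
- **stability trends**: the homolog × feature table with Kendall τ-b trend
  arrows against T_m/T_opt, and aggregation of externally predicted
  per-mutation ΔT_m scores into stabilization hotspots;
- **synthetic data**: ideal-geometry peptide builders, planted-interaction
  fixtures, and fluctuation / two-state / loop-approach trajectory
  generators with machine-readable ground truth, so the full pipeline runs
  and is tested entirely offline.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
stable/floppy homolog pair (a thermophile-like protein with short rigid
loops vs. a psychrophile-like one whose extended first surface loop carries
a 5× fluctuation amplitude next to the active site):

```sh
python analysis/01_generate_homologs.py
python analysis/02_static_features.py
python analysis/03_dynamics.py
python analysis/04_mutation_hotspots.py
```

which prints, among other lines:

```
  helix_percent: stable=72.22 floppy=59.09
  n_long_loops: stable=0.00 floppy=1.00
stable: mean RMSD 0.071 nm, mean Rg 1.434 nm, 2 loops; floppiest loop [25, 28] (RMSF 0.051 nm, 0.22 nm from active site)
floppy: mean RMSD 0.194 nm, mean Rg 2.320 nm, 2 loops; floppiest loop [11, 22] (RMSF 0.2494 nm, 0.229 nm from active site)
two-state trajectory: 2 clusters; RMS histogram peaks near 0.04 nm (within-state) and at the between-state separation
stabilizing: top overall ('E15', 'I', 3.5), top in floppy loop ('S12', 'P', 1.9)
```

Reading: the stable homolog has more helix, no long loop, and a flat RMSF
profile; the floppy homolog's planted 12-residue loop (residues 11–22) is
recovered as the top-ranked floppy loop, sitting ~0.23 nm from the active
site. The two-state trajectory reproduces the bimodal RMS-matrix histogram
expected of a protein hopping between two conformations, and the hotspot
aggregation ranks the strongest stabilizing substitution (E15I, +3.5 K)
first while excluding the catalytic acids. Tables land under `results/`.

The same stages are available as a CLI for real structures, e.g.

```sh
thermostruct parse --pdb 4HMC.pdb --chain A --range 23:339
thermostruct interactions --pdb 1KFW.pdb
thermostruct traj --pdb top.pdb --traj traj.pdb --metric cluster --cutoff 0.5
```

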