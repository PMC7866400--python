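# Methods

This note documents the models, conventions, and numerical choices behind
`thermostruct`, and what the synthetic benchmarks do and do not establish
about real structures.

## Coordinate model and PDB handling

Structures are parsed from PDB text into a Structure → Chain → Residue →
Atom hierarchy. Hydrogens are dropped (the X-ray structures this package
targets have none; all detectors are heavy-atom criteria), waters and
non-protein heteroatoms are discarded, and selenomethionine (MSE) is
renamed to MET with SE→SD so it participates in sequence and sulfur-aware
detectors. Alternate locations are resolved to the highest-occupancy
conformer, ties broken by the lexicographically first altLoc — a
deterministic rule matching common practice. Author residue numbering is
authoritative for all residue references (e.g. "G23–H339" domain
truncation, which accepts a one-letter identity check on the boundary
residues); a 0-based index is used internally for arrays. Missing element
columns are inferred from the first alphabetic character of the atom name.

Sequence identity between homologs uses Biopython's global aligner (match
+1, mismatch 0, gap open −10, gap extend −0.5) and reports identical pairs
over alignment columns, excluding terminal gap overhangs so that a short
homolog aligned inside a longer one is not penalized for the overhang. The
statistic is validated against an exhaustive alignment enumeration on tiny
sequences.

## Composition and isoelectric point

Class fractions use the sequence-analysis convention: charged DEHKR,
hydrophobic GAVLIPMFW, uncharged polar CNQSTY. Note that the *contact*
detector uses a different apolar set (AVLIMFWPY, the interaction-calculator
convention); both are named constants, because conflating them silently
changes hydrophobic-contact counts. Unknown residues ('X') count toward
sequence length but are excluded from class tallies and the charge model.

pI uses the Bjellqvist (ProtParam-compatible) pKa set: side chains D 4.05,
E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus 3.55; N-terminus
7.5 with residue-specific overrides (A 7.59, E 7.70, M 7.00, P 8.36,
S 6.93, T 6.82, V 7.44). Net charge is strictly decreasing in pH, so
bisection on [0, 14] to 1e-4 pH finds the unique root; the result is
cross-checked against a fine-grid charge scan and against Biopython's
implementation of the same convention. Because the N-terminal pKa depends
on the first residue, pI is invariant under interior permutations only.

## Secondary structure

No assignment tool is bundled with deposited structures, so the
Kabsch–Sander rules are implemented natively: amide H rebuilt at ideal
geometry (H = N + unit(C_prev − O_prev)), H-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol accepted below
−0.5, n-turns (n = 3, 4, 5) requiring two consecutive turns to seed a
helix, and parallel/antiparallel bridge patterns marking strands. The
8-state alphabet reduces to 3 states with {H, G, I}→H and {E, B}→E.
Proline cannot donate; chains shorter than 4 residues or residues missing
backbone atoms fall back to coil with a warning. Main-chain H-bonds between
sequence-adjacent residues are not scored (the covalent N(i)···O(i−1)
contact would otherwise register everywhere). Users can also import an
external per-residue state string to reproduce alternative assignments.

Loops are maximal coil runs strictly *between* non-coil elements; terminal
coil is reported separately as a structural proxy for disordered termini,
not counted as loops. "Long" loops exceed 10 residues (configurable).
Helix caps are the single residues flanking a maximal helix run (acidic =
{D, E}, basic = {K, R, H}); "middle of a helix" excludes one helical turn
(3 residues) at each end, so helices shorter than 7 residues have no
middle. Loop counts from different assignment tools differ by a few
segments on real structures; comparisons across homologs should use one
assigner consistently, which is the reason the package reports its own
counts rather than mimicking any specific published tally.

## SASA and burial

Shrake–Rupley with a 1.4 Å water probe, 960 lattice points per atom
(configurable), and Bondi vdW radii (C 1.70, N 1.55, O 1.52, S 1.80 Å).
The lattice is a deterministic golden spiral oriented in the molecule's
principal-axis frame; eigenvector signs are fixed by the third central
moment (skewness) of the coordinate projections, a rotation-equivariant
convention that makes total SASA invariant under rigid motion to better
than 0.1%. Near-spherically-symmetric atom clouds (degenerate covariance
eigenvalues) could defeat this convention; protein coordinates are never
that symmetric in practice. Accuracy: single-sphere areas match
4π(r+probe)² to <0.5%, two-sphere overlaps match the spherical-cap closed
form to ~2% at 960 points, and doubling the lattice moves totals by <1%.

Relative accessibility divides residue SASA by the extended Gly-X-Gly
maxima of Tien et al. (2013, theoretical set). The buried/exposed threshold
defaults to 7% relative accessibility, an interaction-calculator-style
convention; since reference tools rarely document their exact criterion,
the threshold is a parameter and every burial-dependent output records the
value used. Interface area between two chains is
(SASA_A + SASA_B − SASA_AB)/2, computed with one shared lattice orientation
(the complex's principal frame) so that non-contacting chains give exactly
zero; interface residues lose >1 Å² on complexation.

## Interaction detectors

All seven classes are geometric heavy-atom criteria, Å: hydrophobic
side-chain contact ≤5.0 between the apolar set AVLIMFWPY with
sequence-adjacent pairs (|Δseq| ≤ 1, same chain) excluded; H-bonds by
donor–acceptor distance ≤3.5 (O/N) or ≤4.0 (any sulfur member), from
per-residue donor/acceptor atom tables, distance-only by design (the
criteria being reproduced are distances; an optional ≥90° donor-angle
filter exists but is off); salt bridges: Asp/Glu carboxylate O (plus
C-terminal OXT) to Lys NZ / Arg NE,NH1,NH2 / His ND1,NE2 ≤4.0, with the
basic partner (K/R/H) recorded; π–π: ring-centroid separation in
[4.5, 7.0], Trp contributing both rings, a residue pair counted once at
its shortest qualifying distance; cation–π: Lys NZ or the Arg guanidinium
midpoint (mean of CZ, NE, NH1, NH2) to an F/Y/W ring centroid ≤6.0 — a
purely geometric surrogate for energy-filtered cation–π assignment,
flagged as such; π–sulfur: Cys SG / Met SD to centroid ≤5.3; disulfide:
SG–SG ≤2.3. His appearing in a pair that qualifies as a salt bridge is not
also counted as π–π for that pair (salt bridge takes precedence).

Every detector is verified equal to an independent brute-force all-pairs
scan on planted fixtures and random merged structures, invariant under
rigid motion and residue reordering, and monotone in its cutoff. Summaries
report raw counts, per-100-residue normalization (denominator overridable,
e.g. monomer count for a dimer census), buried/exposed/mixed splits from
the burial classification, inter-subunit counts, and the salt-bridge
partner distribution.

## Trajectory metrics

Frames are F×N×3 Å arrays over a topology Structure, read from multi-model
PDB or XYZ (binary formats are out of scope; convert upstream). Metrics
are reported in nm/nm² per MD convention. Superposition is Kabsch via SVD
with the determinant sign correction; degenerate (collinear) point sets are
rejected. RMSD is fitted per frame against frame 0 by default (configurable
reference), on the backbone (N, CA, C, O) selection. RMSF uses a two-pass
fit — fit to frame 0, rebuild the mean, refit to the mean — and reports
per-residue values at CA; with pre-aligned frames and per-coordinate noise
σ the per-atom RMSF converges to √3·σ, which the planted-profile benchmark
recovers within 5% at 10,000 frames. Rg is mass-weighted with standard
atomic masses. The SASA series reuses the surface engine per strided frame.

gromos clustering: pairwise fitted-RMSD matrix on strided frames, then
greedily pop the frame with the most neighbors within the cutoff (default
0.5 nm; ties to the lowest frame index) together with its neighbors as a
cluster. The result is checked against an exhaustive reference
implementation on small frame sets. Stride is specified in frames or
converted from a time stride (e.g. a 5 ns stride at 10 ps spacing → every
500th frame). The RMS-matrix histogram uses 0.02 nm bins over the full
strided upper triangle.

## Floppy loops and occlusion

Loops are ranked by mean member-residue RMSF (ties: peak RMSF, then lower
start index); the top k (default 3) are flagged primary. This is a
reproducible surrogate for what is otherwise partly visual inspection of
trajectories. Proximity to a user-supplied active-site residue list (no
motif auto-detection — guessing catalytic residues would be worse than
requiring them) is the per-frame minimum heavy-atom distance, and the
occlusion flag fires when that distance drops below a threshold after an
equilibration window (default: first 10% of frames excluded, matching
typical tens-of-ns equilibration on a few-hundred-ns trajectory). On
planted approach trajectories the crossing frame is recovered within ±1
frame (the schedule touches the threshold exactly at the planted frame;
the strict `<` test fires one frame later).

## Trend arrows and mutation hotspots

The homolog × feature table gets an arrow per feature: Kendall τ-b against
T_m (primary; T_opt reported alongside since activity optima spread wider
than melting points), ↑ for τ ≥ +0.6, ↓ for τ ≤ −0.6. With five homologs
the ±0.6 threshold admits only near-monotone patterns, mirroring how such
calls are made qualitatively; borderline features (pI is a known offender,
with thermophiles sometimes showing acidic pI) may earn no arrow here
despite a narrative call elsewhere. Per-mutation ΔT_m scores are *input
data* from an external predictor — predicting ΔT_m is explicitly out of
scope — aggregated into per-residue sums and top-k rankings, stabilizing
(descending) or destabilizing (ascending), with a configurable exclusion
list for catalytic residues.

`assemble_report` chains all static stages (plus trajectory means when
frames are given) and writes byte-deterministic TSV/JSON: fixed row/column
order, fixed float format, sorted JSON keys.

## Synthetic data: what it emulates and what it does not

Generators use numpy's default PCG64 generator under an explicit seed;
identical seeds give identical bytes. Peptides are built by internal-
coordinate (NeRF) chaining with ideal bond geometry (N–CA 1.458, CA–C
1.525, C–N 1.329, C=O 1.231 Å; ω = 180°) at prescribed per-residue (φ, ψ);
side chains are truncated at CB — enough for backbone-driven analyses
(secondary structure, RMSF, Rg, clustering), while planted-interaction
fixtures place complete functional groups (rings, carboxylates, amines)
explicitly where a detector needs them, so no rotamer library is required.
The antiparallel hairpin places a 180°-rotated copy of an extended strand
at an offset chosen deterministically to maximize N···O contacts at
H-bonding distance. Trajectory generators add per-residue isotropic
Gaussian noise (optionally wrapped in random rigid motions), mix two
reference conformers with Bernoulli state choice, or translate a loop
toward the active site on a (piecewise-)linear minimum-distance schedule;
all emit their ground truth (σ profiles, state labels, crossing frames)
alongside the frames.

What passing these benchmarks shows: the detectors implement their stated
distance rules exactly; the flexibility and clustering machinery recovers
planted amplitudes, states, and loop identities under Gaussian and
two-state noise. What they do not show: agreement with any particular
third-party tool's census on deposited structures (conventions differ in
undocumented ways — burial criteria, ASA averaging, H-bond networks), nor
realism of the dynamics (no solvent, no correlated motions, no anharmonic
transitions except the explicit two-state mixture). Conclusions about real
homolog families require running the pipeline on real structures and
trajectories; study-scale problem sizes here (tens of residues, 40–10,000
frames, 20 seeds per recovery experiment) were chosen so the whole
evidence chain reruns in seconds.

## Known limitations

- The Kabsch–Sander implementation covers turns, helices, and bridges but
  not the bend (S) and some ladder-merging subtleties of full DSSP; on
  idealized fixtures this is exact, on real structures boundary residues
  of helices/sheets may differ by one position from DSSP output.
- H-bond detection is distance-only; angle-filtered counts will be lower.
- Dimer per-100 normalization is ambiguous across published tools; both
  monomer and assembly denominators are supported and recorded.
- mmCIF, symmetry-generated assemblies, and binary trajectory formats are
  not parsed.
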