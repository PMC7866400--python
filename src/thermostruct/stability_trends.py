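"""Cross-homolog feature assembly, stability trend arrows, and mutation
hotspot aggregation.

A feature earns an "up" arrow when its rank agreement with the stability key
(melting temperature T_m primary, optimum-activity temperature T_opt
secondary) gives Kendall τ-b at or above +0.6, a "down" arrow at or below
-0.6, and no arrow otherwise. Per-mutation ΔT_m scores are input data from
an external predictor; this module only aggregates them into per-residue
sums and top-k rankings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import composition as comp
from . import interactions as ints
from . import secondary_structure as ss_mod
from . import surface_burial as sb
from .structure_io import Structure, extract_sequence


@dataclass
class StabilityRecord:
    protein_id: str
    t_opt: float | None = None   # °C
    t_m: float | None = None     # °C
    class_label: str | None = None  # psychrophilic | mesophilic | thermophilic


@dataclass
class MutationScore:
    protein_id: str
    position: str        # residue reference, e.g. "E357"
    from_aa: str
    to_aa: str
    delta_tm: float      # Kelvin
    region: str = "overall"

    def __post_init__(self):
        if self.from_aa == self.to_aa:
            raise ValueError("mutation must change the residue")


@dataclass
class TrendResult:
    tau: float | None
    arrow: str           # 'up' | 'down' | 'none' | 'insufficient-data'
    n: int


def trend_arrow(feature_values: dict[str, float],
                stability: list[StabilityRecord],
                key: str = "t_m", threshold: float = 0.6) -> TrendResult:
    """Kendall τ-b between a feature and a stability key, mapped to an arrow."""
    xs, ys = [], []
    for rec in stability:
        v = feature_values.get(rec.protein_id)
        stab = getattr(rec, key)
        if v is not None and stab is not None and np.isfinite(v):
            xs.append(v)
            ys.append(stab)
    if len(xs) < 3:
        return TrendResult(None, "insufficient-data", len(xs))
    tau, _ = kendalltau(xs, ys, variant="b")
    if np.isnan(tau):
        return TrendResult(None, "none", len(xs))
    if tau >= threshold:
        arrow = "up"
    elif tau <= -threshold:
        arrow = "down"
    else:
        arrow = "none"
    return TrendResult(float(tau), arrow, len(xs))


def read_mutation_scores(path) -> list[MutationScore]:
    """TSV with columns: protein, position, from, to, delta_tm, region."""
    df = pd.read_csv(path, sep="\t")
    return [
        MutationScore(str(r["protein"]), str(r["position"]), str(r["from"]),
                      str(r["to"]), float(r["delta_tm"]),
                      str(r.get("region", "overall")))
        for _, r in df.iterrows()
    ]


def hotspot_aggregate(scores: list[MutationScore], region: str | None = None,
                      direction: str = "stabilizing", top_k: int = 3,
                      exclude_positions: set[str] | None = None) -> dict:
    """Per-residue ΔT_m sums and the top-k single mutations.

    direction='stabilizing' ranks by delta_tm descending, 'destabilizing'
    ascending. Positions in exclude_positions (e.g. catalytic acids) are
    dropped before ranking.
    """
    if not scores:
        raise ValueError("no mutation scores supplied")
    exclude = exclude_positions or set()
    pool = [s for s in scores
            if (region is None or s.region == region)
            and s.position not in exclude]
    sums: dict[str, float] = {}
    for s in pool:
        sums[s.position] = sums.get(s.position, 0.0) + s.delta_tm
    reverse = direction == "stabilizing"
    ranked_mutations = sorted(pool, key=lambda s: (-s.delta_tm if reverse
                                                   else s.delta_tm,
                                                   s.position, s.to_aa))
    ranked_residues = sorted(sums.items(),
                             key=lambda kv: (-kv[1] if reverse else kv[1], kv[0]))
    return {
        "per_residue_sums": sums,
        "top_mutations": ranked_mutations[:top_k],
        "top_residues": ranked_residues[:top_k],
    }


def _structure_features(s: Structure, cfg: ints.CutoffConfig,
                        burial_threshold: float, n_points: int,
                        per100_chain: str | None = None) -> dict[str, float]:
    seqs = {c.chain_id: extract_sequence(s, c.chain_id) for c in s.chains}
    full_seq = "".join(seqs.values())
    profile = comp.composition_profile(full_seq)
    assignment = ss_mod.assign_ss(s)
    content = ss_mod.ss_content(assignment)
    loops, loop_counts = ss_mod.extract_loops(assignment)
    caps = ss_mod.helix_cap_census(s, assignment)
    sasa = sb.shrake_rupley(s, n_points=n_points)
    burial = sb.classify_burial(s, sasa, threshold=burial_threshold)
    core = sb.core_residue_counts(s, burial)
    detected = ints.detect_all(s, cfg, burial=burial)
    denom = len(seqs[per100_chain]) if per100_chain else None
    summary = ints.summarize(detected, s, n_residues=denom)
    feats = {
        "n_residues": float(s.n_residues),
        "pI": profile.pI,
        "acidic_basic_ratio": profile.acidic_basic_ratio,
        "rk_ratio": profile.rk_ratio,
        "charged_fraction": profile.charged_fraction,
        "hydrophobic_fraction": profile.hydrophobic_fraction,
        "polar_fraction": profile.polar_fraction,
        "helix_percent": content["helix"],
        "strand_percent": content["strand"],
        "coil_percent": content["coil"],
        "total_ss_percent": content["total_SS"],
        "n_loops": float(loop_counts["n_loops"]),
        "n_long_loops": float(loop_counts["n_long_loops"]),
        "n_cap_acidic": float(caps.n_cap_acidic),
        "n_cap_basic": float(caps.n_cap_basic),
        "c_cap_acidic": float(caps.c_cap_acidic),
        "c_cap_basic": float(caps.c_cap_basic),
        "pro_in_helix_middle": float(caps.pro_in_middle),
        "total_sasa_A2": sasa.total,
        "buried_per_100": core["buried_per_100"],
        "buried_hydrophobic_per_100": core["buried_hydrophobic_per_100"],
        "buried_gly": float(core["by_type"].get("G", 0)),
        "buried_ile": float(core["by_type"].get("I", 0)),
    }
    for kind in ints.KINDS:
        feats[f"{kind}_count"] = float(summary.counts[kind])
        feats[f"{kind}_per_100"] = summary.per_100[kind]
        feats[f"{kind}_inter_subunit"] = float(summary.inter_subunit[kind])
    return feats


def assemble_report(structures: dict[str, Structure],
                    stability: list[StabilityRecord],
                    trajectories: dict | None = None,
                    cutoffs: ints.CutoffConfig | None = None,
                    burial_threshold: float = sb.DEFAULT_BURIAL_THRESHOLD,
                    sasa_points: int = sb.DEFAULT_N_POINTS,
                    arrow_threshold: float = 0.6) -> dict:
    """Run all static stages per structure and attach trend arrows.

    Returns {'table': DataFrame (features × proteins), 'arrows': DataFrame,
    'stability': records}. With `trajectories` given ({protein_id:
    Trajectory}), adds mean RMSD/Rg and mean RMSF features.
    """
    if not structures:
        raise ValueError("at least one structure required")
    cfg = cutoffs or ints.CutoffConfig()
    columns = {}
    for pid, s in structures.items():
        try:
            feats = _structure_features(s, cfg, burial_threshold, sasa_points)
        except Exception as exc:
            raise RuntimeError(f"feature stage failed for {pid!r}") from exc
        if trajectories and pid in trajectories:
            from . import trajectory_analysis as ta
            traj = trajectories[pid]
            try:
                feats["mean_rmsd_nm"] = float(np.mean(ta.rmsd_series(traj)))
                feats["mean_rg_nm"] = float(np.mean(ta.rg_series(traj)))
                feats["mean_rmsf_nm"] = float(np.nanmean(ta.rmsf(traj).rmsf))
            except Exception as exc:
                raise RuntimeError(f"trajectory stage failed for {pid!r}") from exc
        columns[pid] = feats
    table = pd.DataFrame(columns).sort_index()
    arrows = {}
    for feat in table.index:
        row = table.loc[feat].to_dict()
        arrows[feat] = {
            key: trend_arrow(row, stability, key=key, threshold=arrow_threshold)
            for key in ("t_m", "t_opt")
        }
    arrow_df = pd.DataFrame({
        key: {feat: arrows[feat][key].arrow for feat in arrows}
        for key in ("t_m", "t_opt")
    }).sort_index()
    return {"table": table, "arrows": arrow_df, "stability": stability}


def write_report(report: dict, outdir) -> dict[str, Path]:
    """Write the feature table and arrows as TSV plus a JSON bundle.

    Output is byte-deterministic for identical inputs: fixed column order,
    fixed float formatting, sorted JSON keys.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table: pd.DataFrame = report["table"].sort_index(axis=0).sort_index(axis=1)
    arrows: pd.DataFrame = report["arrows"].sort_index(axis=0).sort_index(axis=1)
    paths = {}
    paths["features"] = outdir / "features.tsv"
    table.to_csv(paths["features"], sep="\t", float_format="%.6g",
                 lineterminator="\n")
    paths["arrows"] = outdir / "arrows.tsv"
    arrows.to_csv(paths["arrows"], sep="\t", lineterminator="\n")
    bundle = {
        "features": {c: {i: _jsonify(table.at[i, c]) for i in table.index}
                     for c in table.columns},
        "arrows": {c: dict(arrows[c]) for c in arrows.columns},
        "stability": [
            {"protein_id": r.protein_id, "t_m": r.t_m, "t_opt": r.t_opt,
             "class": r.class_label} for r in report["stability"]
        ],
    }
    paths["json"] = outdir / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    return paths


def _jsonify(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return round(v, 6) if isinstance(v, float) else v
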