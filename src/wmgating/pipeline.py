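"""End-to-end orchestration of the gating-EEG analysis cascade.

simulate -> preprocess -> per-condition group ICA -> ICASSO stability
screen -> cross-condition topography matching -> per-pair temporal-
generalization decoding -> cluster permutation inference -> standardized
source contrasts for significant windows -> behavioral gating statistics
-> consolidated report. Stages run in memory; every stage exports its
table/JSON artifact when an output directory is given, so each step can
be inspected and re-run from the library functions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import behavior as beh
from . import clusterperm, corrmap, decode, groupica, icasso, preprocess, sloreta
from .preprocess import CONDITIONS, EpochSet
from .synthdata import SimConfig, simulate_session, trials_to_frame

#: The two gating contrasts: (label, condition A = switch, condition B = nonswitch)
CONTRASTS = (
    ("opening", "switch_reference", "nonswitch_reference"),
    ("closing", "switch_comparison", "nonswitch_comparison"),
)


@dataclass
class PipelineConfig:
    """All cascade parameters; instantiating without overrides yields the
    reference configuration (20 PCs, 50 ICASSO runs, Iq 0.85, |r| 0.9, max 3 per
    group, 5-fold CV x2, 0-1500 ms, 1000/2500 permutations, baseline
    -200..0 ms, 0.5-40 Hz band-pass, 256 Hz)."""

    n_pc: int = 20
    icasso_runs: int = 50
    iq_threshold: float = 0.85
    corr_threshold: float = 0.9
    max_per_group: int = 3
    folds: int = 5
    repeats: int = 2
    decode_tmin: float = 0.0
    decode_tmax: float = 1500.0
    n_perm_cluster: int = 1000
    n_perm_source: int = 2500
    baseline: Tuple[float, float] = (-200.0, 0.0)
    hp: float = 0.5
    lp: float = 40.0
    fs: float = 256.0
    min_trials_per_condition: int = 50
    alpha: float = 0.05
    # desk-scale execution knobs (analysis choices, not study thresholds)
    decode_decim: int = 1
    n_voxels: int = 500
    icasso_clusters: Optional[int] = None  # defaults to n_pc
    ica_max_samples: Optional[int] = None
    ica_max_iter: int = 500
    icasso_max_iter: int = 200
    ica_block: Optional[int] = None  # Infomax minibatch size
    seed: int = 0


@dataclass
class RunReport:
    """Consolidated outcome of one cascade run; every number is traceable
    to a stage artifact written alongside it."""

    behavior: Dict = field(default_factory=dict)
    trial_counts: Dict = field(default_factory=dict)
    excluded_subjects: List = field(default_factory=list)
    condition_iq: Dict = field(default_factory=dict)
    explained_fraction: Dict = field(default_factory=dict)
    pair_tables: Dict = field(default_factory=dict)
    ppaf: Dict = field(default_factory=dict)
    decoding: Dict = field(default_factory=dict)
    significant_windows: List = field(default_factory=list)
    source_contrasts: List = field(default_factory=list)
    seed: int = 0


def _pair_key(contrast: str, pair: corrmap.ComponentPair) -> str:
    return f"{contrast}:IC{pair.ic_a}-IC{pair.ic_b}"


def select_significant_pairs(
    cluster_results: Dict[str, clusterperm.ClusterTestResult],
    times: np.ndarray,
) -> List[Tuple[str, Tuple[float, float], float]]:
    """Forward each pair's significant TG clusters with their bounding
    time window (one entry per cluster, mirroring per-cluster source
    analysis). Returns (pair key, (start ms, end ms), cluster p)."""
    out = []
    times = np.asarray(times, dtype=float)
    for key, res in cluster_results.items():
        shape = res.supra_mask.shape
        for cl in clusterperm.significant_clusters(res):
            ii, jj = np.unravel_index(cl.members, shape)
            lo = float(times[min(ii.min(), jj.min())])
            hi = float(times[max(ii.max(), jj.max())])
            out.append((key, (lo, hi), cl.p_value))
    return out


def run_all(
    sim_cfg: SimConfig,
    cfg: PipelineConfig,
    leadfield: Optional[sloreta.LeadField] = None,
    out_dir=None,
) -> RunReport:
    """Execute the full cascade on a simulated cohort.

    Epochs are simulated at the target rate directly, so the continuous-
    data conditioning steps (band-pass, resampling) do not apply; the
    epoch-level chain (average reference, artifact rejection, baseline
    correction, correct-trial selection) runs in full.
    """
    report = RunReport(seed=cfg.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: simulate cohort --------------------------------------
    all_trials, subj_epochs = [], []
    for s in range(sim_cfg.n_subjects):
        trials, epochs, _gt = simulate_session(sim_cfg, subject_index=s)
        df = trials_to_frame(trials, subject=f"S{s:02d}")
        all_trials.append(df)
        subj_epochs.append((df, epochs))
    trials_df = pd.concat(all_trials, ignore_index=True)
    if out is not None:
        trials_df.to_csv(out / "trials.csv", index=False)

    # ---- stage 2: behavior ---------------------------------------------
    summaries = beh.condition_summaries(trials_df)
    costs = beh.gating_costs(summaries)
    rt_stats = beh.paired_t_and_d(costs["opening_rt"], costs["closing_rt"])
    acc_stats = beh.paired_t_and_d(costs["opening_acc"], costs["closing_acc"])
    report.behavior = {
        "opening_rt_mean": float(costs["opening_rt"].mean()),
        "closing_rt_mean": float(costs["closing_rt"].mean()),
        "opening_acc_mean": float(costs["opening_acc"].mean()),
        "closing_acc_mean": float(costs["closing_acc"].mean()),
        "rt_open_vs_close": rt_stats,
        "acc_open_vs_close": acc_stats,
        "normality_p": {
            col: beh.normality_check(costs[col])
            for col in ("opening_rt", "closing_rt", "opening_acc", "closing_acc")
        },
    }
    if out is not None:
        summaries.to_csv(out / "behavior_summaries.csv", index=False)
        costs.to_csv(out / "gating_costs.csv", index=False)

    # ---- stage 3: preprocess + condition split -------------------------
    cond_epochs: Dict[str, List[EpochSet]] = {c: [] for c in CONDITIONS}
    counts = {}
    for df, epochs in subj_epochs:
        ep = preprocess.average_reference(epochs)
        ep = preprocess.reject_artifacts(ep)
        ep = preprocess.baseline_correct(ep, window=cfg.baseline)
        ep = preprocess.select_correct_trials(ep, df)
        counts[ep.subject] = {
            c: int((ep.condition == c).sum()) for c in CONDITIONS
        }
        for c in CONDITIONS:
            cond_epochs[c].append(ep.select(ep.condition == c))
    counts_df = pd.DataFrame(counts).T
    report.trial_counts = counts
    report.excluded_subjects = preprocess.flag_low_trial_subjects(
        counts_df, min_trials=cfg.min_trials_per_condition
    )
    keep_idx = [
        i
        for i, (df, _) in enumerate(subj_epochs)
        if df["subject"].iloc[0] not in report.excluded_subjects
    ]
    if len(keep_idx) < 6:
        raise RuntimeError(
            "fewer than 6 subjects survive the trial-count screen; "
            "group inference is not possible"
        )
    for c in CONDITIONS:
        kept = [cond_epochs[c][i] for i in keep_idx]
        if any(e.n_trials == 0 for e in kept):
            raise RuntimeError(f"a subject has no trials in condition {c}")
        cond_epochs[c] = kept
    if out is not None:
        counts_df.to_csv(out / "trial_counts.csv")

    # ---- stage 4: per-condition group ICA + ICASSO ---------------------
    ica_results: Dict[str, groupica.GroupICAResult] = {}
    comp_iq: Dict[str, np.ndarray] = {}
    for c in CONDITIONS:
        res = groupica.fit_groupica(
            cond_epochs[c],
            n_pc=cfg.n_pc,
            seed=cfg.seed,
            max_iter=cfg.ica_max_iter,
            max_samples=cfg.ica_max_samples,
            block=cfg.ica_block,
        )
        ica_results[c] = res
        ic_res = icasso.run_icasso(
            res.aggregate_est,
            base_w=res.W,
            r_runs=cfg.icasso_runs,
            n_clusters=cfg.icasso_clusters or cfg.n_pc,
            iq_threshold=cfg.iq_threshold,
            seed=cfg.seed,
            max_iter=cfg.icasso_max_iter,
            block=cfg.ica_block,
        )
        comp_iq[c] = ic_res.component_iq
        report.condition_iq[c] = {
            "mean_iq": float(np.mean(ic_res.component_iq)),
            "component_iq": [float(q) for q in ic_res.component_iq],
            "n_reliable": int(np.sum(ic_res.component_iq >= cfg.iq_threshold)),
        }
        report.explained_fraction[c] = [
            float(p.explained_fraction) for p in res.pca
        ]
    if out is not None:
        pd.DataFrame(
            {c: comp_iq[c] for c in CONDITIONS}
        ).to_csv(out / "component_iq.csv", index_label="component")

    # ---- stage 5: cross-condition matching -----------------------------
    contrast_pairs: Dict[str, List[corrmap.ComponentPair]] = {}
    for label, cond_a, cond_b in CONTRASTS:
        pairs = corrmap.match_topographies(
            ica_results[cond_a].topographies,
            ica_results[cond_b].topographies,
            threshold=cfg.corr_threshold,
            max_per_group=cfg.max_per_group,
            condition_a=cond_a,
            condition_b=cond_b,
        )
        pairs = corrmap.attach_iq(pairs, comp_iq[cond_a], comp_iq[cond_b])
        pairs = corrmap.filter_pairs_by_iq(pairs, cfg.iq_threshold)
        contrast_pairs[label] = pairs
        table = corrmap.pair_report(pairs)
        report.pair_tables[label] = table.to_dict(orient="records")
        if out is not None:
            table.to_csv(out / f"pairs_{label}.csv", index=False)

    # sum of power accounted for by each contrast's selected components
    for label, cond_a, cond_b in CONTRASTS:
        for cond, side in ((cond_a, "ic_a"), (cond_b, "ic_b")):
            subset = sorted({getattr(p, side) for p in contrast_pairs[label]})
            if not subset:
                continue
            vals = []
            for si, ep in enumerate(cond_epochs[cond]):
                x = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
                vals.append(groupica.ppaf(ica_results[cond], subset, si, x))
            report.ppaf[f"{label}:{cond}"] = float(np.mean(vals))

    # ---- stage 6: decoding + cluster inference -------------------------
    dec_times: Optional[np.ndarray] = None
    cluster_results: Dict[str, clusterperm.ClusterTestResult] = {}
    for label, cond_a, cond_b in CONTRASTS:
        for pair in contrast_pairs[label]:
            key = _pair_key(label, pair)
            tgs, aucs = [], []
            for si in range(len(cond_epochs[cond_a])):
                # re-baseline each back-projection: a single component's
                # back-projection is rank-1 across channels, so any fixed
                # offset between the two condition-wise decompositions
                # would be noiselessly separable; per-trial baseline
                # correction cancels constant offsets
                ep_a = preprocess.baseline_correct(
                    groupica.back_project_epochs(
                        ica_results[cond_a], [pair.ic_a], si, cond_epochs[cond_a][si]
                    ),
                    window=cfg.baseline,
                )
                ep_b = preprocess.baseline_correct(
                    groupica.back_project_epochs(
                        ica_results[cond_b], [pair.ic_b], si, cond_epochs[cond_b][si]
                    ),
                    window=cfg.baseline,
                )
                dres = decode.decode_pair(
                    ep_a.data,
                    ep_b.data,
                    times=ep_a.times,
                    tmin=cfg.decode_tmin,
                    tmax=cfg.decode_tmax,
                    folds=cfg.folds,
                    repeats=cfg.repeats,
                    seed=cfg.seed + si,
                    decim=cfg.decode_decim,
                    subject=ep_a.subject,
                    pair=pair,
                )
                dec_times = dres.times
                tgs.append(dres.tg)
                aucs.append(dres.auc_t)
            tg_stack = np.array(tgs)
            auc_stack = np.array(aucs)
            res2d = clusterperm.permutation_test(
                tg_stack,
                n_perm=cfg.n_perm_cluster,
                seed=cfg.seed,
                alpha=cfg.alpha,
            )
            cluster_results[key] = res2d
            mean_auc = auc_stack.mean(axis=0)
            peak = int(np.argmax(mean_auc))
            report.decoding[key] = {
                "peak_auc": float(mean_auc[peak]),
                "peak_time_ms": float(dec_times[peak]),
                "n_subjects": int(auc_stack.shape[0]),
                "n_significant_clusters": len(
                    clusterperm.significant_clusters(res2d)
                ),
            }
            if out is not None:
                pd.DataFrame(
                    {"time_ms": dec_times, "mean_auc": mean_auc}
                ).to_csv(out / f"auc_{key.replace(':', '_')}.csv", index=False)

    # ---- stage 7: significant windows -> source contrasts --------------
    selected = (
        select_significant_pairs(cluster_results, dec_times)
        if dec_times is not None
        else []
    )
    report.significant_windows = [
        {"pair": key, "window_ms": list(win), "p": p} for key, win, p in selected
    ]
    if selected:
        lf = leadfield
        if lf is None:
            n_ch = cond_epochs[CONDITIONS[0]][0].n_channels
            lf = sloreta.make_synthetic_leadfield(
                n_channels=n_ch, n_voxels=cfg.n_voxels, seed=cfg.seed
            )
        pair_lookup = {
            _pair_key(label, p): (label, cond_a, cond_b, p)
            for label, cond_a, cond_b in CONTRASTS
            for p in contrast_pairs[label]
        }
        for key, win, p_cluster in selected:
            label, cond_a, cond_b, pair = pair_lookup[key]
            maps_a, maps_b = [], []
            for si in range(len(cond_epochs[cond_a])):
                for cond, ic, sink in (
                    (cond_a, pair.ic_a, maps_a),
                    (cond_b, pair.ic_b, maps_b),
                ):
                    ep = preprocess.baseline_correct(
                        groupica.back_project_epochs(
                            ica_results[cond], [ic], si, cond_epochs[cond][si]
                        ),
                        window=cfg.baseline,
                    )
                    sink.append(
                        sloreta.window_source_maps(
                            ep.data.mean(axis=0), ep.times, lf, win
                        )
                    )
            contrast = sloreta.snpm_contrast(
                np.array(maps_a),
                np.array(maps_b),
                n_perm=cfg.n_perm_source,
                seed=cfg.seed,
                alpha=cfg.alpha,
            )
            peak_voxel = int(np.argmax(np.abs(contrast.t_map)))
            report.source_contrasts.append(
                {
                    "pair": key,
                    "window_ms": list(win),
                    "cluster_p": p_cluster,
                    "threshold_t": contrast.threshold,
                    "n_significant_voxels": int(contrast.significant_voxels.size),
                    "significant_voxels": contrast.significant_voxels.tolist(),
                    "peak_voxel": peak_voxel,
                    "peak_t": float(contrast.t_map[peak_voxel]),
                    "peak_voxel_coords": [
                        float(v) for v in lf.voxel_coords[peak_voxel]
                    ],
                }
            )
            if out is not None:
                pd.DataFrame(
                    {
                        "voxel": np.arange(lf.n_voxels),
                        "x": lf.voxel_coords[:, 0],
                        "y": lf.voxel_coords[:, 1],
                        "z": lf.voxel_coords[:, 2],
                        "t": contrast.t_map,
                    }
                ).to_csv(
                    out / f"tmap_{key.replace(':', '_')}.csv", index=False
                )

    if out is not None:
        (out / "report.json").write_text(json.dumps(asdict(report), indent=2))
    return report


def demo_setup(
    seed: int = 0, n_subjects: int = 12
) -> Tuple[SimConfig, PipelineConfig, sloreta.LeadField, Tuple[int, int]]:
    """Desk-scale demo: a cohort whose two planted sources are columns of
    a synthetic lead field, so decoding windows AND source localization
    have ground truth.

    Returns (sim_cfg, pipe_cfg, leadfield, (opening voxel, closing voxel)).
    Analysis thresholds (Iq 0.85, |r| 0.9, alpha 0.05, 5-fold CV x2,
    0-1500 ms) are kept; problem sizes (subjects, channels, blocks, PCs,
    ICASSO runs, permutations, voxels, decoding grid) are scaled down.
    """
    from .synthdata import default_sources

    n_channels = 24
    lf = sloreta.make_synthetic_leadfield(
        n_channels=n_channels, n_voxels=200, seed=seed
    )
    # plant sources at two well-separated, strongly seen voxels
    norms = np.linalg.norm(lf.L, axis=0)
    strong = np.argsort(norms)[-50:]
    cols = lf.L[:, strong] / norms[strong]
    best, best_cos = (strong[0], strong[1]), 1.0
    for i in range(len(strong)):
        for j in range(i + 1, len(strong)):
            c = abs(float(cols[:, i] @ cols[:, j]))
            if c < best_cos:
                best_cos = c
                best = (int(strong[i]), int(strong[j]))
    v_open, v_close = best
    topos = np.array(
        [lf.L[:, v_open] / norms[v_open], lf.L[:, v_close] / norms[v_close]]
    )
    sources = default_sources(
        n_channels,
        topographies=topos,
        opening_window=(300.0, 500.0),
        closing_window=(400.0, 750.0),
        effect_amplitude=25.0,
        base_amplitude=15.0,
    )
    sim_cfg = SimConfig(
        n_subjects=n_subjects,
        n_channels=n_channels,
        fs=256.0,
        epoch_window=(-500.0, 1800.0),
        n_blocks=6,
        sources=sources,
        noise_sd=1.0,
        seed=seed,
    )
    pipe_cfg = PipelineConfig(
        n_pc=8,
        icasso_runs=10,
        n_perm_cluster=200,
        n_perm_source=200,
        min_trials_per_condition=10,
        decode_decim=2,
        n_voxels=200,
        ica_max_samples=16000,
        ica_max_iter=300,
        icasso_max_iter=200,
        ica_block=512,
        seed=seed,
    )
    return sim_cfg, pipe_cfg, lf, (v_open, v_close)
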