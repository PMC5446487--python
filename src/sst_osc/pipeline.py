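"""End-to-end synthetic study: behavior -> model fit -> EEG -> cluster statistics.

``run_study`` reproduces the full trial-by-trial analysis on a simulated
cohort: it generates stop-signal behavior for every subject, fits the
observer per subject and averages the fitted parameters, re-derives each
subject's P(stop)/PE trace with those group parameters, synthesizes epoched
EEG for the three event locks, runs the Morlet decomposition with baseline
correction, builds within-subject z-maps, and evaluates the five
covariate-by-lock group cluster tests — the three planted pairs
(P(stop) x fixation, go-RT x go, PE x stop) and the two null pairs
(P(stop) x go, go-RT x fixation) whose dissociation is the study's
signature.  It also correlates the mean power of the P(stop) and go-RT
clusters across trials, re-tests the PE pair after residualizing
stop-outcome condition means, and writes behavioral summaries plus a
machine-readable JSON report.  Everything derives from one master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as tio
from .behavior_sim import RaceConfig, TaskConfig, simulate_cohort
from .cluster_stats import (
    cluster_power_correlation,
    group_cluster_test,
    regress_out_condition_means,
    subject_zmap,
)
from .eeg_sim import EEGSimConfig, reject_artifacts, simulate_epochs
from .fit import FitGrid, fit_subject, group_average_params
from .metrics import estimate_critical_ssd, ssrt
from .observer import ObserverParams, run_sequence
from .timefreq import TFConfig, TFEpochs, baseline_correct, morlet_transform

logger = logging.getLogger("sst_osc.pipeline")

__all__ = ["StudyConfig", "run_study"]

#: covariate x lock pairs tested at group level (planted + null pairs)
TESTED_PAIRS = [
    ("pstop", "fixation"),
    ("rt_ms", "go"),
    ("pe", "stop"),
    ("pstop", "go"),
    ("rt_ms", "fixation"),
]

#: per-lock analysis windows (s, event-locked) over which z-maps are built
ANALYSIS_WINDOWS = {"fixation": (0.0, 0.5), "go": (0.0, 0.8), "stop": (0.0, 0.5)}


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one synthetic study."""

    n_subjects: int = 18
    task: TaskConfig = field(default_factory=TaskConfig)
    race: RaceConfig = field(default_factory=RaceConfig)
    observer: ObserverParams = field(
        default_factory=lambda: ObserverParams(alpha=0.78, pm=0.14, sc=10.0)
    )
    fit_grid: FitGrid = field(default_factory=FitGrid)
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)
    tf: TFConfig = field(default_factory=TFConfig)
    cluster_thresholds: tuple[float, ...] = (0.02, 0.005, 0.001)
    n_perm_subject: int = 1000
    n_iter_group: int = 2000
    master_seed: int = 0
    fit_observer: bool = True  # refit per subject vs reuse the generative params

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        """Build a config from a (YAML-friendly) nested dict of overrides."""
        kwargs: dict = {}
        sub = {
            "task": TaskConfig,
            "race": RaceConfig,
            "observer": ObserverParams,
            "fit_grid": FitGrid,
            "eeg": EEGSimConfig,
            "tf": TFConfig,
        }
        for key, val in d.items():
            if key in sub:
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _crop_time(tf: TFEpochs, window: tuple[float, float]) -> TFEpochs:
    sel = (tf.times_s >= window[0] - 1e-9) & (tf.times_s <= window[1] + 1e-9)
    return TFEpochs(
        power=tf.power[:, :, sel],
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s[sel],
        lock=tf.lock,
        trial_index=tf.trial_index,
        baseline_applied=tf.baseline_applied,
    )


def _aligned_covariate(trials: pd.DataFrame, tf: TFEpochs, name: str):
    """Subset a TF tensor to epochs whose covariate is finite; return both."""
    cov = trials.loc[tf.trial_index, name].to_numpy(dtype=float)
    ok = np.isfinite(cov)
    sub = TFEpochs(
        power=tf.power[ok],
        freqs_hz=tf.freqs_hz,
        times_s=tf.times_s,
        lock=tf.lock,
        trial_index=tf.trial_index[ok],
        baseline_applied=tf.baseline_applied,
    )
    return sub, cov[ok]


def _cluster_row(zmap, cluster) -> dict:
    f = zmap.freqs_hz[cluster.bins[:, 0]]
    t = zmap.times_s[cluster.bins[:, 1]]
    return {
        "n_bins": len(cluster.bins),
        "freq_lo_hz": float(f.min()),
        "freq_hi_hz": float(f.max()),
        "time_lo_s": float(t.min()),
        "time_hi_s": float(t.max()),
        "summed_t": cluster.summed_t,
        "sign": cluster.sign,
        "p_perm": cluster.p_perm,
    }


def _behavioral_summary(cohort, group_params) -> dict:
    rows = []
    for tab in cohort:
        go = tab[tab["trial_type"] == "go"]
        st = tab[tab["trial_type"] == "stop"]
        go_ok = tab[(tab["outcome"] == "go_success") & np.isfinite(tab["rt_ms"])]
        fit = estimate_critical_ssd(tab)
        seq_r = stats.pearsonr(go_ok["pstop"], go_ok["rt_ms"])[0]
        rows.append(
            {
                "go_success_rate": (go["outcome"] == "go_success").mean(),
                "go_rt_ms": go_ok["rt_ms"].mean(),
                "stop_success_rate": (st["outcome"] == "stop_success").mean(),
                "stop_error_rt_ms": st.loc[st["outcome"] == "stop_error", "rt_ms"].mean(),
                "critical_ssd_ms": fit.critical_ssd_ms,
                "ssrt_ms": ssrt(tab, fit),
                "sequential_r": seq_r,
            }
        )
    df = pd.DataFrame(rows)
    out = {k: float(df[k].mean()) for k in df.columns}
    out["n_subjects"] = len(cohort)
    return out


def run_study(cfg: StudyConfig, outdir) -> dict:
    """Run the full synthetic study; write artifacts and return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.master_seed)
    summary: dict = {"master_seed": cfg.master_seed}
    t_start = time.time()

    def stage(name):
        logger.info("stage %-22s t=%.1fs", name, time.time() - t_start)

    try:
        stage("simulate-behavior")
        cohort = simulate_cohort(
            cfg.n_subjects, cfg.task, cfg.race, cfg.observer, seed=cfg.master_seed
        )

        stage("fit-observer")
        if cfg.fit_observer:
            fits = [fit_subject(tab, cfg.fit_grid, readout=cfg.observer.readout)
                    for tab in cohort]
            group_params = group_average_params(fits)
            summary["fit"] = {
                "alpha": group_params.alpha,
                "pm": group_params.pm,
                "sc": group_params.sc,
                "mean_best_r": float(np.mean([f.best_r for f in fits])),
            }
        else:
            group_params = cfg.observer

        stage("attach-pstop")
        for tab in cohort:
            s = (tab["trial_type"] == "stop").to_numpy().astype(int)
            trace = run_sequence(s, group_params)
            tab["pstop"], tab["pe"] = trace.pstop, trace.pe
        for i, tab in enumerate(cohort):
            tio.save_trials(outdir / f"subject{i:02d}_trials.csv", tab)

        stage("behavioral-summary")
        summary["behavior"] = _behavioral_summary(cohort, group_params)

        stage("simulate-eeg+tfr")
        tf_by_lock: dict[str, list[TFEpochs]] = {lock: [] for lock in ANALYSIS_WINDOWS}
        for si, tab in enumerate(cohort):
            srng = np.random.default_rng(master.integers(2**31))
            for lock in ANALYSIS_WINDOWS:
                ep = simulate_epochs(tab, cfg.eeg, lock, srng)
                ep = reject_artifacts(ep, 150.0, window_s=cfg.tf.crop_window_s)
                tf = baseline_correct(morlet_transform(ep, cfg.tf), cfg.tf)
                tf_by_lock[lock].append(tf)

        stage("zmaps+cluster-tests")
        zrng = np.random.default_rng(master.integers(2**31))
        results: dict[str, dict] = {}
        zmaps_by_pair = {}
        for covname, lock in TESTED_PAIRS:
            zmaps = []
            for si, tab in enumerate(cohort):
                tfc = _crop_time(tf_by_lock[lock][si], ANALYSIS_WINDOWS[lock])
                sub, cov = _aligned_covariate(tab, tfc, covname)
                zmaps.append(
                    subject_zmap(sub, cov, covname, n_perm=cfg.n_perm_subject, rng=zrng)
                )
            zmaps_by_pair[(covname, lock)] = zmaps
            pair_res = {}
            for thr in cfg.cluster_thresholds:
                res = group_cluster_test(zmaps, thr, cfg.n_iter_group, rng=zrng)
                rows = [_cluster_row(zmaps[0], c) for c in res.clusters]
                pair_res[str(thr)] = {
                    "min_p_perm": res.min_p if res.clusters else None,
                    "clusters": rows,
                }
                if rows:
                    pd.DataFrame(rows).to_csv(
                        outdir / f"clusters_{covname}_{lock}_thr{thr}.csv", index=False
                    )
            results[f"{covname}|{lock}"] = pair_res
        summary["cluster_tests"] = results

        stage("cluster-power-correlation")
        summary["cluster_power_correlation"] = _power_correlation(
            cfg, cohort, tf_by_lock, zmaps_by_pair, zrng
        )

        stage("pe-residualized")
        summary["pe_residualized"] = _pe_residualized(cfg, cohort, tf_by_lock, zrng)

        summary["dissociation"] = _dissociation(results, cfg.cluster_thresholds[0])
        with open(outdir / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, default=float)
        stage("done")
        return summary
    except Exception:
        logger.exception("study aborted")
        raise


def _power_correlation(cfg, cohort, tf_by_lock, zmaps_by_pair, rng):
    """Across-trial correlation of the P(stop)- and RT-cluster mean powers."""
    # recover the observed clusters from fresh tests at the strictest
    # threshold that yields one (the planted pairs normally do at 0.005)
    out = {}
    picks = {}
    for covname, lock in (("pstop", "fixation"), ("rt_ms", "go")):
        zmaps = zmaps_by_pair[(covname, lock)]
        for thr in sorted(cfg.cluster_thresholds):
            res = group_cluster_test(zmaps, thr, cfg.n_iter_group, rng=rng)
            sig = [c for c in res.clusters if c.p_perm < 0.05]
            if sig:
                picks[lock] = max(sig, key=lambda c: abs(c.summed_t))
                break
    if set(picks) != {"fixation", "go"}:
        return {"note": "no significant cluster available in one of the pairs"}
    tfs_a = [_crop_time(tf, ANALYSIS_WINDOWS["fixation"]) for tf in tf_by_lock["fixation"]]
    tfs_b = [_crop_time(tf, ANALYSIS_WINDOWS["go"]) for tf in tf_by_lock["go"]]
    res = cluster_power_correlation(
        tfs_a, picks["fixation"].bins, tfs_b, picks["go"].bins
    )
    return {
        "median_r": res.median_r,
        "wilcoxon_p": res.wilcoxon_p,
        "normality_p": res.ks_p,
        "coefficients": res.coefficients.tolist(),
    }


def _pe_residualized(cfg, cohort, tf_by_lock, rng):
    """PE correlation after removing stop-success/stop-error mean power."""
    zmaps = []
    for si, tab in enumerate(cohort):
        tfc = _crop_time(tf_by_lock["stop"][si], ANALYSIS_WINDOWS["stop"])
        sub, cov = _aligned_covariate(tab, tfc, "pe")
        cond = tab.loc[sub.trial_index, "outcome"].to_numpy()
        resid = regress_out_condition_means(sub, cond)
        zmaps.append(subject_zmap(resid, cov, "pe", n_perm=cfg.n_perm_subject, rng=rng))
    res = group_cluster_test(zmaps, cfg.cluster_thresholds[0], cfg.n_iter_group, rng=rng)
    return {
        "min_p_perm": res.min_p if res.clusters else None,
        "n_clusters": len(res.clusters),
    }


def _dissociation(results: dict, threshold: float) -> dict:
    """Significance pattern of the planted vs null covariate x lock pairs."""
    def sig(pair):
        p = results[pair][str(threshold)]["min_p_perm"]
        return p is not None and p < 0.05

    pattern = {
        "pstop_fixation_significant": sig("pstop|fixation"),
        "rt_go_significant": sig("rt_ms|go"),
        "pe_stop_significant": sig("pe|stop"),
        "pstop_go_significant": sig("pstop|go"),
        "rt_fixation_significant": sig("rt_ms|fixation"),
    }
    pattern["dissociation_holds"] = (
        pattern["pstop_fixation_significant"]
        and pattern["rt_go_significant"]
        and not pattern["pstop_go_significant"]
        and not pattern["rt_fixation_significant"]
    )
    return pattern
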