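"""End-to-end orchestration: simulate → behavior → spectral → cluster → biomarker.

``run_all`` executes the full workflow on a synthetic cohort and writes tidy
CSV tables, a JSON cluster inventory, figures, and a provenance stamp
(package version, config hash, seed) into the output directory. Stages can
be skipped; any stage failure aborts with a stage-named error while earlier
outputs are preserved.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from cogdbs import behavior, biomarker, cluster, simulate, spectral
from cogdbs.config import RunConfig

logger = logging.getLogger(__name__)

STAGES = ["simulate", "behavior", "spectral", "cluster", "biomarker", "resting"]


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _write_provenance(out: Path, cfg: RunConfig) -> None:
    from cogdbs import __version__

    out.mkdir(parents=True, exist_ok=True)
    (out / "run_info.json").write_text(
        json.dumps(
            {
                "package": "cogdbs",
                "version": __version__,
                "config_hash": cfg.hash(),
                "seed": cfg.seed,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
            indent=2,
        )
    )
    cfg.to_yaml(out / "config.yaml")


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sim = cfg.sim.replace(seed=cfg.seed)
    trials = simulate.simulate_trials(sim)
    trials.to_csv(out / "trials.csv", index=False)
    return {"sim": sim, "trials": trials}


def stage_behavior(cfg: RunConfig, state: dict, out: Path) -> dict:
    trials = state["trials"]
    clean, report = behavior.qc_filter(trials)
    spec, trace = behavior.stepwise_aic(
        clean, cfg.behavior_candidates, cfg.behavior_nuisance
    )
    res = behavior.fit_gamma_glm(clean, spec)
    table = res.fixed_effects().reset_index(names="term")
    table.to_csv(out / "behavior_coefficients.csv", index=False)
    err = trials[~trials.get("missing", pd.Series(False, index=trials.index)).fillna(False)]
    on = err[err["dbs"] == "ON"]
    off = err[err["dbs"] == "OFF"]
    p_err = behavior.binomial_error_test(
        int((~on["correct"]).sum()), len(on), int((~off["correct"]).sum()), len(off)
    )
    (out / "behavior_qc.json").write_text(
        json.dumps({"qc": report, "aic_trace": trace, "error_rate_p": p_err}, indent=2)
    )
    mean_rt = float(clean["rt"].mean())
    logger.info("behavior: selected terms %s, mean RT %.0f ms", spec.fixed_terms, mean_rt)
    return {
        "clean_trials": clean,
        "qc_report": report,
        "behavior_spec": spec,
        "behavior_results": res,
        "error_rate_p": p_err,
        "mean_rt_ms": mean_rt,
    }


def stage_spectral(cfg: RunConfig, state: dict, out: Path) -> dict:
    """Per-subject epochs → QC → ERP subtraction → TFR → dB band power.

    Only the EEG subcohort (first ``n_subjects_eeg`` subjects) contributes,
    mirroring cohorts in which not every subject yields analyzable EEG.
    Processing streams one subject at a time to bound memory.
    """
    sim = state["sim"]
    trials = state["clean_trials"]
    subjects = sorted(trials["subject"].unique())[: cfg.n_subjects_eeg]
    bp_all, meta_all = [], []
    erp_example = None
    n_rejected = 0
    for i, subj in enumerate(subjects):
        sub_trials = trials[trials["subject"] == subj].reset_index(drop=True)
        epochs = simulate.simulate_epochs(
            sub_trials, sim, seed=int(np.random.SeedSequence([cfg.seed, 23, i]).generate_state(1)[0] % (2**31))
        )
        epochs, bad = spectral.amplitude_reject(epochs, cfg.amplitude_threshold)
        n_rejected += len(bad)
        induced = spectral.subtract_erp(epochs)
        tfr = spectral.morlet_tfr(
            induced,
            freqs=spectral.default_freqs(cfg.tfr_fmin, cfg.tfr_fmax, cfg.tfr_n_freqs),
            n_cycles=cfg.tfr_n_cycles,
            decim=cfg.tfr_decim,
        )
        bp = spectral.band_average(tfr, cfg.bands)
        bp = spectral.db_normalize(bp, cfg.baseline)
        bp_all.append(bp.power.astype(np.float32))
        meta_all.append(bp.trial_meta)
        if erp_example is None:
            erp_example = spectral.erp_pipeline(epochs)
        times, bands, labels, valid = bp.times, bp.bands, bp.label_names, bp.valid
    power = np.concatenate(bp_all, axis=0)
    meta = pd.concat(meta_all, ignore_index=True)
    logger.info(
        "spectral: %d trials from %d subjects, %d rejected for amplitude",
        len(meta), len(subjects), n_rejected,
    )
    return {
        "band_power": power,
        "bp_meta": meta,
        "bp_times": times,
        "bands": bands,
        "labels": labels,
        "bp_valid": valid,
        "erp_example": erp_example,
        "n_amplitude_rejected": n_rejected,
    }


def stage_cluster(cfg: RunConfig, state: dict, out: Path) -> dict:
    """Sliding OLS + cluster-mass permutation per label × band, FDR across both."""
    power = state["band_power"]
    meta = state["bp_meta"]
    times = state["bp_times"]
    tmask = (times >= cfg.analysis_window[0]) & (times <= cfg.analysis_window[1])
    times_a = times[tmask]
    design = cluster.design_from_trials(meta)
    all_clusters: list[cluster.Cluster] = []
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 29]))
    for bi, band in enumerate(state["bands"]):
        for li, label in enumerate(state["labels"]):
            model = cluster.SingleTrialRegression(
                power[:, bi, li, :][:, tmask].astype(float),
                design,
                meta["subject"].to_numpy(),
                times_a,
            )
            for predictor in ("dbs", "interference"):
                cl = model.permutation_test(
                    predictor,
                    n_perm=cfg.n_perm,
                    seed=int(rng.integers(2**31)),
                    alpha_cluster=cfg.cluster_alpha,
                    min_duration=cfg.min_cluster_duration,
                )
                for c in cl:
                    c.label, c.band = label, band
                all_clusters.extend(cl)
    # FDR across ROIs and bands, separately per predictor
    for predictor in ("dbs", "interference"):
        cluster.apply_fdr([c for c in all_clusters if c.predictor == predictor])
    inventory = [c.to_dict() for c in all_clusters]
    (out / "cluster_inventory.json").write_text(json.dumps(inventory, indent=2))

    mean_rt_s = state["mean_rt_ms"] / 1000.0
    window = (state["sim"].msit_onset, state["sim"].msit_onset + mean_rt_s)
    sig_theta = [
        c
        for c in all_clusters
        if c.band == "theta" and c.p_fdr is not None and c.p_fdr < 0.05
    ]
    frac = cluster.cluster_mass_fraction(sig_theta, times_a, window)
    logger.info(
        "cluster: %d clusters (%d significant theta), %.1f%% of theta mass "
        "in the decision window", len(all_clusters), len(sig_theta), frac,
    )
    return {
        "clusters": all_clusters,
        "cluster_times": times_a,
        "theta_mass_fraction": frac,
        "decision_window": window,
    }


def _dbs_theta_window(state: dict) -> tuple[float, float]:
    """Integration window for the biomarker: the significant DBS theta
    cluster in VLPFC, else the largest-mass DBS theta cluster anywhere,
    else the post-stimulus decision window."""
    cands = [
        c for c in state["clusters"]
        if c.predictor == "dbs" and c.band == "theta" and c.p_perm is not None
    ]
    vl = [c for c in cands if c.label == "VLPFC" and (c.p_fdr or 1) < 0.05]
    if vl:
        best = max(vl, key=lambda c: abs(c.mass))
        return best.t_start, best.t_end
    sig = [c for c in cands if (c.p_fdr or 1) < 0.05]
    if sig:
        best = max(sig, key=lambda c: abs(c.mass))
        logger.warning("no significant VLPFC DBS theta cluster; using %s", best.label)
        return best.t_start, best.t_end
    logger.warning("no significant DBS theta cluster; using decision window")
    return state["decision_window"]


def stage_biomarker(cfg: RunConfig, state: dict, out: Path) -> dict:
    power = state["band_power"]
    meta = state["bp_meta"]
    times = state["bp_times"]
    bi = state["bands"].index("theta")
    li = state["labels"].index("VLPFC") if "VLPFC" in state["labels"] else 0
    window = _dbs_theta_window(state)

    rows = []
    for subj, grp in meta.groupby("subject"):
        idx = np.asarray(grp.index)
        on = idx[(grp["dbs"] == "ON").to_numpy()]
        off = idx[(grp["dbs"] == "OFF").to_numpy()]
        theta_on = power[on, bi, li, :].mean(axis=0)
        theta_off = power[off, bi, li, :].mean(axis=0)
        d_theta = biomarker.integrate_theta_difference(theta_on, theta_off, times, window)
        trials = state["clean_trials"]
        st = trials[trials["subject"] == subj]
        d_rt = float(
            st.loc[st["dbs"] == "ON", "rt"].mean() - st.loc[st["dbs"] == "OFF", "rt"].mean()
        )
        rows.append({"subject": subj, "delta_theta": d_theta, "delta_rt": d_rt})
    tab = pd.DataFrame(rows)
    clinical = simulate.simulate_clinical_given_theta(
        tab["delta_theta"].to_numpy(), state["sim"], subjects=list(tab["subject"]),
        seed=cfg.seed,
    )
    tab = tab.merge(clinical.drop(columns=["delta_theta"]), on="subject")
    tab.to_csv(out / "subject_biomarkers.csv", index=False)
    results = biomarker.evaluate_biomarkers(tab, n_boot=cfg.n_boot, seed=cfg.seed)
    serializable = {
        k: (
            {kk: vv for kk, vv in v.items() if not kk.startswith("roc")}
            if isinstance(v, dict)
            else v
        )
        for k, v in results.items()
    }
    (out / "biomarker_results.json").write_text(json.dumps(serializable, indent=2))
    return {"biomarker_table": tab, "biomarker_results": results, "theta_window": window}


def stage_resting(cfg: RunConfig, state: dict, out: Path) -> dict:
    sim = state["sim"]
    on = simulate.simulate_resting(sim, 61.0, "ON", seed=cfg.seed)
    off = simulate.simulate_resting(sim, 61.0, "OFF", seed=cfg.seed)
    res = spectral.resting_theta_compare(on[0], off[0], sim.sampling_rate)
    (out / "resting_results.json").write_text(
        json.dumps({"U": res["U"], "p": res["p"]}, indent=2)
    )
    return {"resting": res}


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def make_figures(state: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # RT by condition (behavioral effects)
    trials = state["clean_trials"]
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    for ax, fac, order in (
        (axes[0], "interference", [0, 1]),
        (axes[1], "dbs", ["OFF", "ON"]),
    ):
        means = trials.groupby(fac)["rt"].mean().reindex(order)
        sems = trials.groupby(fac)["rt"].sem().reindex(order)
        ax.bar([str(o) for o in order], means, yerr=sems, color="steelblue")
        ax.set_ylabel("RT (ms)")
        ax.set_title(fac)
        ax.set_ylim(means.min() - 100, means.max() + 100)
    fig.tight_layout()
    fig.savefig(out / "fig_behavior_rt.png", dpi=120)
    plt.close(fig)

    # theta time course with significant clusters (VLPFC)
    if "band_power" in state:
        power, meta, times = state["band_power"], state["bp_meta"], state["bp_times"]
        bi = state["bands"].index("theta")
        li = state["labels"].index("VLPFC") if "VLPFC" in state["labels"] else 0
        fig, ax = plt.subplots(figsize=(6, 3))
        for stname, color in (("ON", "crimson"), ("OFF", "gray")):
            m = (meta["dbs"] == stname).to_numpy()
            ax.plot(times, power[m, bi, li, :].mean(axis=0), color=color, label=stname)
        for c in state.get("clusters", []):
            if c.band == "theta" and c.label == state["labels"][li] and (c.p_fdr or 1) < 0.05:
                ax.axvspan(c.t_start, c.t_end, color="k", alpha=0.1)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("theta power (dB)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "fig_theta_timecourse.png", dpi=120)
        plt.close(fig)

    # biomarker scatter + ROC
    if "biomarker_table" in state:
        tab = state["biomarker_table"]
        res = state["biomarker_results"]["delta_theta"]
        fig, axes = plt.subplots(1, 2, figsize=(7, 3))
        x = tab["delta_theta"]
        y = -tab["madrs_change"]
        axes[0].scatter(x, y, c="k")
        xs = np.linspace(x.min(), x.max(), 10)
        axes[0].plot(xs, res["slope"] * xs + res["intercept"], "r-")
        axes[0].set_xlabel("ON−OFF theta (dB·s)")
        axes[0].set_ylabel("MADRS improvement")
        axes[0].set_title(f"r = {res['r']:.2f}, p = {res['p']:.3f}")
        if "roc_responder" in res:
            fpr, tpr, _ = res["roc_responder"]
            axes[1].plot(fpr, tpr, "b-")
            axes[1].plot([0, 1], [0, 1], "k--")
            axes[1].set_xlabel("FPR")
            axes[1].set_ylabel("TPR")
            axes[1].set_title(f"AUC = {res['auc_responder']:.2f}")
        fig.tight_layout()
        fig.savefig(out / "fig_biomarker.png", dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the accumulated state dict."""
    out = Path(cfg.out_dir)
    _write_provenance(out, cfg)
    state: dict = {}
    stage_fns = {
        "simulate": stage_simulate,
        "behavior": stage_behavior,
        "spectral": stage_spectral,
        "cluster": stage_cluster,
        "biomarker": stage_biomarker,
        "resting": stage_resting,
    }
    skipped: set[str] = set()
    for stage in STAGES:
        if stage in cfg.skip:
            logger.info("skipping stage %s", stage)
            skipped.add(stage)
            continue
        deps = {
            "behavior": ["simulate"],
            "spectral": ["behavior"],
            "cluster": ["spectral"],
            "biomarker": ["cluster"],
            "resting": ["simulate"],
        }.get(stage, [])
        # skipping propagates transitively through the dependency chain
        if any(d in skipped for d in deps):
            logger.info("skipping stage %s (dependency skipped)", stage)
            skipped.add(stage)
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                state.update(stage_fns[stage](cfg, out))
            else:
                state.update(stage_fns[stage](cfg, state, out))
        except Exception as exc:  # preserve partial outputs
            raise StageError(stage, exc) from exc
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    if cfg.make_figures and "clean_trials" in state:
        make_figures(state, out)
    _write_summary(state, out)
    return state


def _write_summary(state: dict, out: Path) -> None:
    summary: dict = {}
    if "behavior_results" in state:
        fe = state["behavior_results"].fixed_effects()
        summary["behavior"] = {
            term: {"coef_ms": float(fe.loc[term, "coef"]), "wald_t": float(fe.loc[term, "wald_t"]), "p": float(fe.loc[term, "p"])}
            for term in fe.index
        }
        summary["behavior"]["error_rate_p"] = state["error_rate_p"]
    if "clusters" in state:
        summary["n_clusters"] = len(state["clusters"])
        summary["n_significant_theta_clusters"] = len(
            [c for c in state["clusters"] if c.band == "theta" and (c.p_fdr or 1) < 0.05]
        )
        summary["theta_mass_fraction_pct"] = state["theta_mass_fraction"]
    if "biomarker_results" in state:
        r = state["biomarker_results"]["delta_theta"]
        summary["biomarker"] = {
            "r": r["r"],
            "p": r["p"],
            "auc_responder": r.get("auc_responder"),
        }
    if "resting" in state:
        summary["resting_p"] = state["resting"]["p"]
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
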