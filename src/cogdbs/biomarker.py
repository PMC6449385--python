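"""Per-subject ON−OFF biomarkers and their clinical validation.

The candidate biomarkers are (a) the mean DBS ON − OFF reaction-time change
and (b) the integrated height of the ON − OFF induced-theta difference wave
in ventrolateral PFC over the window where the group-level cluster analysis
found a significant DBS effect. These are correlated with MADRS change
(Pearson r, p by Fisher Z-transform), displayed with a robust (Huber) line,
given bootstrap CIs over subjects, and evaluated as classifiers of clinical
response (≥50% MADRS drop) and of hypomania via ROC/AUC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve


def integrate_theta_difference(
    theta_on: np.ndarray,
    theta_off: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
) -> float:
    """Trapezoidal integral (dB·s) of the ON − OFF theta difference wave."""
    times = np.asarray(times, dtype=float)
    m = (times >= window[0]) & (times <= window[1])
    if m.sum() < 2:
        raise ValueError(f"window {window} covers fewer than 2 samples")
    diff = np.asarray(theta_on, dtype=float)[m] - np.asarray(theta_off, dtype=float)[m]
    return float(np.trapezoid(diff, times[m]))


def pearson_fisher(x=None, y=None, r: float | None = None, n: int | None = None):
    """Pearson correlation with a Fisher Z-transform p-value.

    Either pass two samples, or pass ``r`` and ``n`` directly to get the p
    for an already-computed correlation. Two-sided p from
    ``z = atanh(r)·sqrt(n − 3)`` against the standard normal.
    """
    if r is None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing pairs are not allowed")
        n = len(x)
        if n < 4:
            raise ValueError("need at least 4 pairs")
        r = float(np.corrcoef(x, y)[0, 1])
    elif n is None or n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(r), float(p)


def robust_line(x, y, tuning: float = 1.345):
    """Huber M-estimator line fit; returns (slope, intercept).

    Used for display and effect direction; inference comes from
    :func:`pearson_fisher` and the bootstrap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(x)
    res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=tuning)).fit()
    intercept, slope = res.params
    return float(slope), float(intercept)


def make_bootstrap_draws(n: int, n_boot: int = 1000, seed: int = 0) -> np.ndarray:
    """Subject-index resamples (with replacement), shape (n_boot, n).

    Generate once and reuse across statistics so their CIs share draws.
    """
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_boot, n))


def bootstrap_ci(
    statistic,
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    draws: np.ndarray | None = None,
    ci: float = 95.0,
):
    """Percentile bootstrap CI of ``statistic(table)`` over subject resamples.

    ``statistic`` maps a DataFrame to a scalar; resamples yielding NaN
    (e.g. a degenerate correlation) are dropped from the percentile.
    """
    if draws is None:
        draws = make_bootstrap_draws(len(table), n_boot, seed)
    vals = np.empty(len(draws))
    for b, idx in enumerate(draws):
        try:
            vals[b] = statistic(table.iloc[idx].reset_index(drop=True))
        except Exception:
            vals[b] = np.nan
    vals = vals[np.isfinite(vals)]
    lo, hi = np.percentile(vals, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(lo), float(hi)


def roc_auc(scores, labels):
    """ROC AUC with midrank tie handling.

    Returns (auc, (fpr, tpr, thresholds)). The AUC equals the normalized
    Mann–Whitney U: the probability a random positive outranks a random
    negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need both positive and negative labels")
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(_sk_auc(fpr, tpr)), (fpr, tpr, thr)


def evaluate_biomarkers(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Full biomarker stage on a per-subject table.

    Expects columns ``delta_theta`` (dB·s), ``delta_rt`` (ms),
    ``madrs_change`` (follow-up − baseline; negative = improvement),
    ``responder`` (bool) and optionally ``hypomania`` (nullable bool;
    missing subjects are dropped row-wise from hypomania analyses).

    Correlations are against MADRS improvement (−``madrs_change``). The same
    bootstrap draws are reused across all statistics.
    """
    t = table.reset_index(drop=True)
    improvement = -t["madrs_change"].to_numpy(float)
    draws = make_bootstrap_draws(len(t), n_boot, seed)
    out: dict = {"n": len(t)}

    for name in ("delta_theta", "delta_rt"):
        x = t[name].to_numpy(float)
        r, p = pearson_fisher(x, improvement)
        slope, intercept = robust_line(x, improvement)
        r_ci = bootstrap_ci(
            lambda d, name=name: pearson_fisher(
                d[name].to_numpy(float), -d["madrs_change"].to_numpy(float)
            )[0],
            t,
            draws=draws,
        )
        out[name] = {
            "r": r,
            "p": p,
            "r_ci": r_ci,
            "slope": slope,
            "intercept": intercept,
        }
        if t["responder"].astype(bool).nunique() == 2:
            a, curve = roc_auc(x, t["responder"])
            a_ci = bootstrap_ci(
                lambda d, name=name: roc_auc(d[name], d["responder"])[0],
                t,
                draws=draws,
            )
            out[name]["auc_responder"] = a
            out[name]["auc_responder_ci"] = a_ci
            out[name]["roc_responder"] = curve
        if "hypomania" in t.columns:
            h = t.dropna(subset=["hypomania"])
            if h["hypomania"].astype(bool).nunique() == 2:
                a, curve = roc_auc(h[name], h["hypomania"].astype(bool))
                a_ci = bootstrap_ci(
                    lambda d, name=name: roc_auc(
                        d.dropna(subset=["hypomania"])[name],
                        d.dropna(subset=["hypomania"])["hypomania"].astype(bool),
                    )[0],
                    t,
                    draws=draws,
                )
                out[name]["auc_hypomania"] = a
                out[name]["auc_hypomania_ci"] = a_ci
    return out
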