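"""Single-trial sliding regression with cluster-mass permutation inference.

At every timepoint the single-trial voltage or band power is regressed on
the experimental variables (interference, DBS, valence, arousal, trial
number, and a DBS × interference interaction), all standardized to [0, 1],
after each subject's all-trials mean time course has been subtracted
(mirroring a subject random intercept). Contiguous runs where the |t| of a
predictor exceeds the two-sided cluster-forming threshold, lasting at least
50 ms, are summarized by their signed t mass and tested against the
permutation distribution of the maximum |cluster mass|, with the predictor
of interest permuted within subject. Cluster p-values are then
Benjamini–Hochberg corrected across ROIs (and frequency bands, for the
spectral path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

#: Predictors of the standard single-trial design.
DEFAULT_PREDICTORS = [
    "interference",
    "dbs",
    "valence",
    "arousal",
    "trial",
    "interference:dbs",
]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def design_from_trials(meta: pd.DataFrame, predictors=DEFAULT_PREDICTORS) -> pd.DataFrame:
    """Standardized [0, 1] design matrix (no intercept) from trial metadata.

    ``a:b`` entries are products of the standardized main-effect columns;
    binary text columns (e.g. DBS ON/OFF) are dummy coded.
    """
    cols = {}

    def scaled(name: str) -> np.ndarray:
        raw = meta[name]
        if raw.dtype == object or str(raw.dtype) == "category":
            levels = sorted(map(str, pd.unique(raw)))
            if len(levels) > 2:
                raise ValueError(f"predictor {name!r} has >2 levels: {levels}")
            return (raw.astype(str) == levels[-1]).to_numpy(float)
        x = raw.to_numpy(float)
        lo, hi = x.min(), x.max()
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    for term in predictors:
        if ":" in term:
            a, b = term.split(":")
            cols[term] = scaled(a) * scaled(b)
        else:
            cols[term] = scaled(term)
    return pd.DataFrame(cols, index=meta.index)


# ---------------------------------------------------------------------------
# Subject demeaning and sliding OLS
# ---------------------------------------------------------------------------

def subject_demean(data: np.ndarray, subjects) -> np.ndarray:
    """Subtract each subject's all-trials mean time course from their trials."""
    data = np.asarray(data, dtype=float)
    out = data.copy()
    subjects = np.asarray(subjects)
    for s in np.unique(subjects):
        m = subjects == s
        out[m] -= data[m].mean(axis=0)
    return out


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in np.where(diag <= tol)[0]]


def sliding_ols(data: np.ndarray, design: pd.DataFrame):
    """Per-timepoint OLS of trials × time data on the design (plus intercept).

    Returns (betas, tvals): arrays of shape (n_predictors, n_times), in the
    design's column order. t = beta / SE with df = n − p − 1 where p is the
    number of predictors.
    """
    data = np.asarray(data, dtype=float)
    n, T = data.shape
    names = list(design.columns)
    p = len(names)
    if n <= p + 1:
        raise ValueError(f"need n_trials > n_predictors + 1 ({n} <= {p + 1})")
    X = np.column_stack([np.ones(n), design.to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, ["Intercept"] + names)
        raise ValueError(f"design rank deficient; collinear columns: {bad}")
    beta, t, _ = _ols_arrays(X, data)
    return beta[1:], t[1:]


def _ols_arrays(X: np.ndarray, Y: np.ndarray):
    """Vectorized OLS over all timepoints; returns (beta, t, df)."""
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)          # k × T
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return beta, t, df


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A contiguous suprathreshold run of one sign in a t time course."""

    start: int                    # first sample index
    stop: int                     # last sample index (inclusive)
    t_start: float                # s
    t_end: float                  # s
    mass: float                   # signed sum of t over the run
    sign: int
    samples: np.ndarray = field(repr=False, default=None)
    t_values: np.ndarray = field(repr=False, default=None)
    p_perm: float | None = None
    p_fdr: float | None = None
    label: str | None = None
    band: str | None = None
    predictor: str | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "band": self.band,
            "predictor": self.predictor,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "mass": self.mass,
            "sign": "+" if self.sign > 0 else "-",
            "p_perm": self.p_perm,
            "p_fdr": self.p_fdr,
        }


def form_clusters(
    t_series: np.ndarray,
    times: np.ndarray,
    df: int,
    alpha_cluster: float = 0.05,
    min_duration: float = 0.05,
) -> list[Cluster]:
    """Contiguous same-sign runs of |t| above the two-sided critical value.

    Runs shorter than ``min_duration`` seconds (duration = n_samples /
    sampling rate) are discarded. Cluster mass is the signed sum of t.
    """
    t_series = np.asarray(t_series, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    crit = sps.t.ppf(1 - alpha_cluster / 2, df)
    supra = np.abs(t_series) > crit
    sign = np.sign(t_series)
    clusters: list[Cluster] = []
    i = 0
    T = len(t_series)
    while i < T:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < T and supra[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        n_samp = j - i + 1
        if n_samp * dt >= min_duration:
            idx = np.arange(i, j + 1)
            clusters.append(
                Cluster(
                    start=i,
                    stop=j,
                    t_start=float(times[i]),
                    t_end=float(times[j]),
                    mass=float(t_series[i : j + 1].sum()),
                    sign=int(sign[i]),
                    samples=idx,
                    t_values=t_series[idx].copy(),
                )
            )
        i = j + 1
    return clusters


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

class SingleTrialRegression:
    """Sliding OLS model for one label's trials × time data.

    Parameters
    ----------
    data : ndarray (n_trials, n_times)
        Single-trial voltage or band power. Subject-demeaned internally
        unless ``demean=False``.
    design : DataFrame
        Standardized predictors (see :func:`design_from_trials`).
    subjects : array-like
        Subject id per trial; defines the within-subject permutation blocks.
    times : ndarray
        Seconds, one per column of ``data``.
    """

    def __init__(self, data, design: pd.DataFrame, subjects, times, demean: bool = True):
        subjects = np.asarray(subjects)
        data = np.asarray(data, dtype=float)
        design = design.reset_index(drop=True)
        counts = pd.Series(subjects).value_counts()
        small = counts[counts < 2].index.tolist()
        if small:
            warnings.warn(
                f"excluding subjects with <2 trials from permutation: {small}",
                stacklevel=2,
            )
            keep = ~np.isin(subjects, small)
            data, subjects = data[keep], subjects[keep]
            design = design.loc[keep].reset_index(drop=True)
        self.subjects = subjects
        self.design = design
        self.times = np.asarray(times, dtype=float)
        self.data = subject_demean(data, subjects) if demean else data
        self._X = np.column_stack(
            [np.ones(len(self.design)), self.design.to_numpy(float)]
        )
        self._names = ["Intercept"] + list(self.design.columns)
        if np.linalg.matrix_rank(self._X) < self._X.shape[1]:
            bad = _collinear_columns(self._X, self._names)
            raise ValueError(f"design rank deficient; collinear columns: {bad}")
        self._blocks = [
            np.where(self.subjects == s)[0] for s in np.unique(self.subjects)
        ]

    @property
    def df(self) -> int:
        return self.data.shape[0] - self._X.shape[1]

    def fit(self):
        """Observed betas and t per (predictor, timepoint)."""
        beta, t, _ = _ols_arrays(self._X, self.data)
        return (
            pd.DataFrame(beta[1:], index=self.design.columns),
            pd.DataFrame(t[1:], index=self.design.columns),
        )

    def permutation_test(
        self,
        predictor: str,
        n_perm: int = 1000,
        seed: int = 0,
        alpha_cluster: float = 0.05,
        min_duration: float = 0.05,
        scheme: str = "manly",
    ) -> list[Cluster]:
        """Cluster-mass permutation test of one predictor.

        The null distribution is built by permuting the predictor-of-
        interest column within subject (other covariates fixed; ``scheme=
        "manly"``) or, with ``scheme="freedman-lane"``, by permuting reduced
        -model residuals within subject, refitting the full model each time
        and recording the maximum |cluster mass| over time. The observed
        clusters get ``p_perm = (1 + #{null >= |mass|}) / (n_perm + 1)``.
        """
        if predictor not in self.design.columns:
            raise KeyError(f"predictor {predictor!r} not in design")
        if scheme not in ("manly", "freedman-lane"):
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        rng = np.random.default_rng(seed)
        pcol = list(self.design.columns).index(predictor) + 1  # +1 intercept
        beta, t, _ = _ols_arrays(self._X, self.data)
        t_obs = t[pcol]
        clusters = form_clusters(
            t_obs, self.times, self.df, alpha_cluster, min_duration
        )
        for c in clusters:
            c.predictor = predictor

        if scheme == "freedman-lane":
            Xr = np.delete(self._X, pcol, axis=1)
            beta_r = np.linalg.lstsq(Xr, self.data, rcond=None)[0]
            fitted_r = Xr @ beta_r
            resid_r = self.data - fitted_r

        null_max = np.zeros(n_perm)
        X = self._X.copy()
        for b in range(n_perm):
            perm = np.arange(self.data.shape[0])
            for blk in self._blocks:
                perm[blk] = blk[rng.permutation(len(blk))]
            if scheme == "manly":
                X[:, pcol] = self._X[perm, pcol]
                _, t_null, _ = _ols_arrays(X, self.data)
            else:
                Y = fitted_r + resid_r[perm]
                _, t_null, _ = _ols_arrays(self._X, Y)
            null_clusters = form_clusters(
                t_null[pcol], self.times, self.df, alpha_cluster, min_duration
            )
            if null_clusters:
                null_max[b] = max(abs(c.mass) for c in null_clusters)
        for c in clusters:
            c.p_perm = float(
                (1 + np.sum(null_max >= abs(c.mass))) / (n_perm + 1)
            )
        return clusters


def permutation_cluster_test(
    data,
    design: pd.DataFrame,
    subjects,
    times,
    predictor: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha_cluster: float = 0.05,
    min_duration: float = 0.05,
    scheme: str = "manly",
) -> list[Cluster]:
    """Functional wrapper around :class:`SingleTrialRegression`."""
    model = SingleTrialRegression(data, design, subjects, times)
    return model.permutation_test(
        predictor, n_perm, seed, alpha_cluster, min_duration, scheme
    )


# ---------------------------------------------------------------------------
# FDR and summaries
# ---------------------------------------------------------------------------

def fdr_stepdown(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (across ROIs × bands)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def apply_fdr(clusters: list[Cluster]) -> list[Cluster]:
    """Attach BH-adjusted p-values across a cluster collection in place."""
    if clusters:
        adj = fdr_stepdown([c.p_perm for c in clusters])
        for c, a in zip(clusters, adj):
            c.p_fdr = float(max(a, c.p_perm))
    return clusters


def cluster_mass_fraction(clusters: list[Cluster], times, window: tuple[float, float]) -> float:
    """Percentage of summed |cluster mass| lying inside a time window.

    Partial overlap counts the |t| of the in-window samples only; the
    denominator is the total |t| mass across all clusters (and labels).
    """
    times = np.asarray(times, dtype=float)
    total = 0.0
    inside = 0.0
    for c in clusters:
        tvals = np.abs(c.t_values)
        total += tvals.sum()
        m = (times[c.samples] >= window[0]) & (times[c.samples] <= window[1])
        inside += tvals[m].sum()
    if total == 0:
        return float("nan")
    return 100.0 * inside / total
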