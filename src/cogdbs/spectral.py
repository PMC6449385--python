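"""ERP pipeline, Morlet time–frequency decomposition, and induced power.

The central measure is induced (non-phase-locked) band power: the mean ERP
for each subject × condition × label is subtracted from every trial before
wavelet decomposition, so only activity that does not survive trial
averaging contributes. Power is normalized in dB to a pre-stimulus baseline
computed separately per subject and DBS condition, and the same
stimulus-locked baseline serves response-locked epochs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from mne.filter import filter_data
from mne.time_frequency import psd_array_multitaper, tfr_array_morlet

from cogdbs.config import BANDS
from cogdbs.epochs import EpochArray

DEFAULT_BASELINE = (-0.5, -0.1)

#: Trial-grouping columns defining a "condition" for ERP computation.
ERP_GROUPS = ["subject", "dbs", "interference"]


# ---------------------------------------------------------------------------
# Epoch QC
# ---------------------------------------------------------------------------

def amplitude_reject(epochs: EpochArray, threshold: float = 150.0):
    """Drop trials containing any sample exceeding ±threshold.

    Returns (cleaned EpochArray, indices of rejected trials).
    """
    bad = np.where(np.any(np.abs(epochs.data) > threshold, axis=(1, 2)))[0]
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    return epochs.select_trials(keep), bad


# ---------------------------------------------------------------------------
# Evoked / induced decomposition
# ---------------------------------------------------------------------------

def _group_keys(meta: pd.DataFrame, group_by) -> pd.Series:
    cols = [c for c in group_by if c in meta.columns]
    if not cols:
        return pd.Series(["all"] * len(meta), index=meta.index)
    return meta[cols].astype(str).agg("|".join, axis=1)


def compute_erp(epochs: EpochArray, group_by=ERP_GROUPS) -> dict[str, np.ndarray]:
    """Mean time course per subject × condition × label group.

    Returns a dict mapping group key to an array (n_labels, n_times).
    """
    keys = _group_keys(epochs.trial_meta, group_by)
    return {
        k: epochs.data[idx.to_numpy()].mean(axis=0)
        for k, idx in keys.groupby(keys).groups.items()
    }


def subtract_erp(
    epochs: EpochArray,
    erps: dict[str, np.ndarray] | None = None,
    group_by=ERP_GROUPS,
) -> EpochArray:
    """Remove each trial's group-mean ERP, leaving non-phase-locked activity."""
    if erps is None:
        erps = compute_erp(epochs, group_by)
    keys = _group_keys(epochs.trial_meta, group_by)
    out = epochs.copy()
    for i, k in enumerate(keys):
        out.data[i] -= erps[k]
    return out


# ---------------------------------------------------------------------------
# Morlet time-frequency decomposition
# ---------------------------------------------------------------------------

def default_freqs(fmin: float = 2.0, fmax: float = 50.0, n: int = 25) -> np.ndarray:
    """Base-10 log-spaced wavelet center frequencies, endpoints included."""
    return np.logspace(math.log10(fmin), math.log10(fmax), n)


@dataclass
class TFR:
    """Single-trial wavelet power: trials × freqs × labels × time.

    ``valid`` marks, per (freq, time), samples free of convolution edge
    effects (within (n_cycles/2)/f of an epoch edge is invalid).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    label_names: list[str]
    valid: np.ndarray
    lock: str = "stimulus"
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)


def morlet_tfr(
    epochs: EpochArray,
    freqs: np.ndarray | None = None,
    n_cycles: float = 3.0,
    decim: int = 1,
) -> TFR:
    """Per-trial Morlet wavelet power.

    Wavelets have ``n_cycles`` cycles at each of 25 log-spaced base
    frequencies between 2 and 50 Hz by default. The epoch is reflect-padded
    by half the longest wavelet before convolution and edge-contaminated
    samples are flagged in ``valid`` rather than silently returned.
    """
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    fmin = freqs.min()
    wavelet_halfwidth = (n_cycles / 2.0) / fmin  # s
    duration = epochs.times[-1] - epochs.times[0]
    if duration < n_cycles / fmin:
        raise ValueError(
            f"epoch ({duration:.2f} s) shorter than the {fmin:g} Hz wavelet "
            f"({n_cycles / fmin:.2f} s)"
        )
    n_pad = int(np.ceil(wavelet_halfwidth * epochs.sfreq))
    padded = np.pad(epochs.data, ((0, 0), (0, 0), (n_pad, n_pad)), mode="reflect")
    power = tfr_array_morlet(
        padded,
        sfreq=epochs.sfreq,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        zero_mean=True,
    )
    power = power[:, :, :, n_pad : n_pad + epochs.n_times]  # crop padding
    # (trials, labels, freqs, time) -> (trials, freqs, labels, time)
    power = np.transpose(power, (0, 2, 1, 3))

    times = epochs.times
    if decim > 1:
        power = power[..., ::decim]
        times = times[::decim]
    half = (n_cycles / 2.0) / freqs
    valid = (times[None, :] >= epochs.times[0] + half[:, None]) & (
        times[None, :] <= epochs.times[-1] - half[:, None]
    )
    return TFR(
        power,
        freqs,
        times,
        epochs.sfreq / decim,
        list(epochs.label_names),
        valid,
        epochs.lock,
        epochs.trial_meta.copy(),
    )


# ---------------------------------------------------------------------------
# Band power and dB normalization
# ---------------------------------------------------------------------------

@dataclass
class BandPower:
    """Band-averaged power: trials × bands × labels × time.

    Values are linear power after :func:`band_average` and dB re baseline
    after :func:`db_normalize`.
    """

    power: np.ndarray
    bands: list[str]
    times: np.ndarray
    sfreq: float
    label_names: list[str]
    valid: np.ndarray            # bands × time
    unit: str = "power"
    lock: str = "stimulus"
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)


def band_average(tfr: TFR, bands: dict[str, tuple[float, float]] | None = None) -> BandPower:
    """Average wavelet power over the grid frequencies inside each band."""
    bands = dict(BANDS) if bands is None else bands
    names, arrs, valids = [], [], []
    for name, (lo, hi) in bands.items():
        m = (tfr.freqs >= lo) & (tfr.freqs <= hi)
        if not m.any():
            raise ValueError(f"no grid frequencies inside band {name} ({lo}-{hi} Hz)")
        names.append(name)
        arrs.append(tfr.power[:, m].mean(axis=1))
        valids.append(tfr.valid[m].all(axis=0))
    power = np.stack(arrs, axis=1)  # trials × bands × labels × time
    return BandPower(
        power,
        names,
        tfr.times,
        tfr.sfreq,
        list(tfr.label_names),
        np.stack(valids),
        "power",
        tfr.lock,
        tfr.trial_meta.copy(),
    )


def compute_baseline(
    bp: BandPower,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    group_by=("subject", "dbs"),
) -> dict[str, np.ndarray]:
    """Mean baseline power per group: group key -> (bands, labels) array.

    The baseline is the average power over the pre-stimulus window across
    that group's trials, computed separately per subject and DBS condition.
    """
    if bp.unit != "power":
        raise ValueError("baseline must be computed on linear power")
    tmask = (bp.times >= baseline[0]) & (bp.times <= baseline[1])
    if not tmask.any():
        raise ValueError(f"baseline window {baseline} not covered by epochs")
    keys = _group_keys(bp.trial_meta, group_by)
    out = {}
    for k, idx in keys.groupby(keys).groups.items():
        out[k] = bp.power[np.asarray(idx)][:, :, :, tmask].mean(axis=(0, 3))
    return out


def db_normalize(
    bp: BandPower,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    group_by=("subject", "dbs"),
    baselines: dict[str, np.ndarray] | None = None,
) -> BandPower:
    """Convert band power to dB re the pre-stimulus baseline.

    Pass precomputed ``baselines`` (from stimulus-locked epochs) to reuse
    the same baseline for response-locked data.
    """
    if baselines is None:
        baselines = compute_baseline(bp, baseline, group_by)
    keys = _group_keys(bp.trial_meta, group_by)
    out = bp.power.copy()
    for i, k in enumerate(keys):
        out[i] = 10.0 * np.log10(out[i] / baselines[k][:, :, None])
    return BandPower(
        out,
        list(bp.bands),
        bp.times,
        bp.sfreq,
        list(bp.label_names),
        bp.valid.copy(),
        "dB",
        bp.lock,
        bp.trial_meta.copy(),
    )


# ---------------------------------------------------------------------------
# Time-domain (ERP) pipeline
# ---------------------------------------------------------------------------

def erp_pipeline(
    epochs: EpochArray,
    window: tuple[float, float] | None = None,
    lowpass: float = 15.0,
    downsample: int = 3,
) -> EpochArray:
    """Time-domain analysis path: crop, 15 Hz low-pass, downsample by 3.

    Default windows are (−0.5, 2.0) s stimulus-locked and (−1.0, 1.0) s
    response-locked.
    """
    if window is None:
        window = (-0.5, 2.0) if epochs.lock == "stimulus" else (-1.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filt = filter_data(
            epochs.data, epochs.sfreq, None, lowpass, verbose="error"
        )
    out = EpochArray(
        filt,
        epochs.times,
        epochs.sfreq,
        list(epochs.label_names),
        epochs.lock,
        epochs.trial_meta.copy(),
    ).crop(*window)
    out.data = out.data[:, :, ::downsample]
    out.times = out.times[::downsample]
    out.sfreq = epochs.sfreq / downsample
    return out


def bootstrap_erp_ci(
    epochs: EpochArray,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
):
    """Bootstrap CI of the grand-mean ERP.

    Trials are resampled with replacement within each subject (preserving
    per-subject trial counts); the grand mean is the mean of subject means.
    Returns (grand_mean, lo, hi), each (n_labels, n_times).
    """
    rng = np.random.default_rng(seed)
    meta = epochs.trial_meta
    subj = meta["subject"] if "subject" in meta.columns else pd.Series(["all"] * epochs.n_trials)
    groups = [np.asarray(ix) for _, ix in subj.groupby(subj).groups.items()]
    subj_means = np.stack([epochs.data[g].mean(axis=0) for g in groups])
    grand = subj_means.mean(axis=0)
    boots = np.empty((n_boot,) + grand.shape)
    for b in range(n_boot):
        means = [
            epochs.data[g[rng.integers(len(g), size=len(g))]].mean(axis=0)
            for g in groups
        ]
        boots[b] = np.mean(means, axis=0)
    lo, hi = np.percentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2], axis=0)
    return grand, lo, hi


# ---------------------------------------------------------------------------
# Resting state
# ---------------------------------------------------------------------------

def cut_rest_epochs(trace: np.ndarray, sfreq: float, epoch_len: float = 1.0, n_epochs: int = 60) -> np.ndarray:
    """Cut the first ``n_epochs`` non-overlapping epochs from a 1-D trace."""
    nper = int(round(epoch_len * sfreq))
    total = nper * n_epochs
    if len(trace) < total:
        raise ValueError(
            f"trace too short: need {total} samples for {n_epochs} epochs, "
            f"have {len(trace)}"
        )
    return trace[:total].reshape(n_epochs, nper)


def resting_theta_compare(
    trace_on: np.ndarray,
    trace_off: np.ndarray,
    sfreq: float,
    epoch_len: float = 1.0,
    n_epochs: int = 60,
    band: tuple[float, float] = (4.0, 8.0),
    bandwidth: float = 8.0,
):
    """ON vs OFF resting theta via multitaper PSD and Mann–Whitney U.

    Cuts ``n_epochs`` epochs of ``epoch_len`` seconds per condition,
    computes a multitaper PSD from 0 to 30 Hz per epoch, averages power in
    the theta band, and tests the two distributions of per-epoch theta
    means.

    Returns a dict with per-epoch theta means, the U statistic, and p.
    """
    res = {}
    for key, trace in (("on", trace_on), ("off", trace_off)):
        ep = cut_rest_epochs(np.asarray(trace, dtype=float), sfreq, epoch_len, n_epochs)
        psd, freqs = psd_array_multitaper(
            ep, sfreq, fmin=0.0, fmax=30.0, bandwidth=bandwidth, verbose="error"
        )
        m = (freqs >= band[0]) & (freqs <= band[1])
        res[f"theta_{key}"] = psd[:, m].mean(axis=1)
    u, p = sps.mannwhitneyu(res["theta_on"], res["theta_off"], alternative="two-sided")
    res["U"] = float(u)
    res["p"] = float(p)
    return res
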