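"""Synthetic cohorts for the conflict-task DBS analysis.

Generates everything the analysis stages consume: counterbalanced MSIT trial
sequences with emotional-picture ratings, gamma-distributed reaction times
with interference and DBS effects, epoched ROI time courses built from 1/f
noise plus a phase-locked evoked component plus non-phase-locked theta
bursts, resting-state segments, and per-subject clinical tables with a
tunable theta/outcome linkage.

The defaults encode the study conditions: two 144-trial blocks (72 control +
72 interference each), one per DBS state, interference slowing responses by
224 ms, DBS ON speeding them by 34 ms, and DBS boosting induced theta.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cogdbs.config import SimConfig
from cogdbs.epochs import EpochArray

VALENCE_CATEGORIES = ("negative", "neutral", "positive")

#: Representative picture-level (valence, arousal) rating centers per
#: category on the 1–9 self-assessment scale.
_CATEGORY_RATINGS = {
    "negative": (2.5, 6.0),
    "neutral": (5.0, 3.5),
    "positive": (7.5, 5.5),
}


class InfeasibleSequenceError(RuntimeError):
    """Raised when no trial ordering can satisfy the run-length constraints."""


def valence_category(rating: float) -> str:
    """Map a 1–9 valence rating to negative/neutral/positive."""
    if rating < 4.0:
        return "negative"
    if rating <= 6.0:
        return "neutral"
    return "positive"


# ---------------------------------------------------------------------------
# Trial sequences
# ---------------------------------------------------------------------------

def _window_violations(seq: list[dict]) -> int:
    """Count length-3 windows where any attribute is identical across all 3."""
    bad = 0
    for i in range(len(seq) - 2):
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        for key in ("valence_cat", "interference", "finger"):
            if a[key] == b[key] == c[key]:
                bad += 1
                break
    return bad


def generate_trial_sequence(
    n_control: int,
    n_interference: int,
    valences=None,
    seed: int | np.random.Generator = 0,
    max_restarts: int = 500,
) -> list[dict]:
    """Pseudo-randomized MSIT trial sequence.

    Produces ``n_control + n_interference`` trial skeletons such that no
    three consecutive trials share the same valence category, the same
    interference level, or the same response finger. Built by randomized
    greedy selection with bounded restarts.

    Parameters
    ----------
    valences : sequence of str, optional
        Valence category per trial (values from
        ``{"negative","neutral","positive"}``), length ``n_control +
        n_interference``. Default: balanced across the three categories.

    Returns
    -------
    list of dict with keys ``interference`` (0/1), ``valence_cat``,
    ``finger`` (1–3).

    Raises
    ------
    InfeasibleSequenceError
        If no valid ordering is found within ``max_restarts`` attempts
        (e.g. all trials one type with a single finger and n >= 3).
    """
    n = n_control + n_interference
    if n < 0:
        raise ValueError("trial counts must be nonnegative")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)

    if valences is None:
        reps = math.ceil(n / 3)
        valences = list(itertools.islice(itertools.cycle(VALENCE_CATEGORIES), n)) if reps else []
    valences = list(valences)
    if len(valences) != n:
        raise ValueError(f"need {n} valence labels, got {len(valences)}")
    bad = set(valences) - set(VALENCE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown valence categories: {sorted(bad)}")

    fingers = list(itertools.islice(itertools.cycle((1, 2, 3)), n))
    interference = [0] * n_control + [1] * n_interference
    items = [
        {"interference": i, "valence_cat": v, "finger": f}
        for i, v, f in zip(interference, valences, fingers)
    ]

    for _ in range(max_restarts):
        pool = list(items)
        rng.shuffle(pool)
        seq: list[dict] = []
        dead_end = False
        while pool:
            # candidates that do not create a triple-identical window
            ok = []
            for j, it in enumerate(pool):
                if len(seq) >= 2:
                    a, b = seq[-2], seq[-1]
                    if any(
                        a[k] == b[k] == it[k]
                        for k in ("valence_cat", "interference", "finger")
                    ):
                        continue
                ok.append(j)
            if not ok:
                dead_end = True
                break
            seq.append(pool.pop(ok[rng.integers(len(ok))]))
        if not dead_end:
            assert _window_violations(seq) == 0
            return seq
    raise InfeasibleSequenceError(
        f"no ordering satisfying the run-length constraints found in "
        f"{max_restarts} attempts ({n_control} control / {n_interference} "
        "interference trials)"
    )


# ---------------------------------------------------------------------------
# Image-set splitting
# ---------------------------------------------------------------------------

def split_objective(ratings: np.ndarray, set_a, set_b) -> float:
    """Mean squared valence difference between rank-matched images.

    Each set is rank-ordered by valence; the objective is the mean squared
    difference between the i-th ranked valence in one set and the other.
    """
    ratings = np.asarray(ratings, dtype=float)
    va = np.sort(ratings[list(set_a), 0])
    vb = np.sort(ratings[list(set_b), 0])
    return float(np.mean((va - vb) ** 2))


def split_images(ratings, seed: int | np.random.Generator = 0):
    """Split an even-sized image pool into two rating-matched halves.

    Images are rank-ordered by valence, consecutive pairs are formed, and
    one image of each pair goes to each set (randomized within pair). For a
    valence-based rank-matched squared-difference objective this adjacent
    pairing is optimal.

    Returns
    -------
    (set_a, set_b) : two index arrays of length n/2.
    """
    ratings = np.asarray(ratings, dtype=float).reshape(len(ratings), -1)
    n = len(ratings)
    if n % 2:
        raise ValueError(f"image count must be even, got {n}")
    rng = np.random.default_rng(seed)
    order = np.argsort(ratings[:, 0], kind="stable")
    set_a, set_b = [], []
    for i in range(0, n, 2):
        pair = [order[i], order[i + 1]]
        if rng.integers(2):
            pair.reverse()
        set_a.append(pair[0])
        set_b.append(pair[1])
    return np.array(set_a), np.array(set_b)


def make_image_pool(n_images: int = 144, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Emotional-picture pool with valence/arousal ratings covering 1–9.

    One third of the pool per valence category, ratings jittered around the
    category centers and clipped to the 1–9 scale.
    """
    rng = np.random.default_rng(seed)
    per = n_images // 3
    counts = [per, per, n_images - 2 * per]
    rows = []
    for cat, cnt in zip(VALENCE_CATEGORIES, counts):
        v0, a0 = _CATEGORY_RATINGS[cat]
        v = np.clip(rng.normal(v0, 0.8, cnt), 1, 9)
        a = np.clip(rng.normal(a0, 1.0, cnt), 1, 9)
        for vi, ai in zip(v, a):
            rows.append({"valence": vi, "arousal": ai, "category": cat})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trial tables & reaction times
# ---------------------------------------------------------------------------

def make_trial_table(config: SimConfig) -> pd.DataFrame:
    """Full-cohort trial table (no RTs yet).

    One block of ``n_control + n_interference`` trials per DBS state per
    ``n_blocks_per_state``, per subject. Valence/arousal ratings are drawn
    per subject around image-category means (subjects rate pictures
    idiosyncratically), with subject rating noise SD 0.5.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    n_per_block = config.n_control + config.n_interference
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        block_id = 0
        for state in ("ON", "OFF"):
            for _ in range(config.n_blocks_per_state):
                block_id += 1
                seq = generate_trial_sequence(
                    config.n_control,
                    config.n_interference,
                    seed=rng,
                )
                for t, item in enumerate(seq, start=1):
                    v0, a0 = _CATEGORY_RATINGS[item["valence_cat"]]
                    rows.append(
                        {
                            "subject": subject,
                            "block": block_id,
                            "dbs": state,
                            "trial": t,
                            "interference": item["interference"],
                            "valence_cat": item["valence_cat"],
                            "valence": float(np.clip(rng.normal(v0, 0.5), 1, 9)),
                            "arousal": float(np.clip(rng.normal(a0, 0.5), 1, 9)),
                            "finger": item["finger"],
                        }
                    )
        assert block_id == 2 * config.n_blocks_per_state
    df = pd.DataFrame(rows)
    df["n_block_trials"] = n_per_block
    return df


def simulate_rts(trials: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Fill a trial table with gamma reaction times, errors and misses.

    RT ~ Gamma(shape=``rt_shape``) with identity-link mean
    ``rt_intercept + effect_interference·interference + effect_dbs·[dbs==ON]
    + subject intercept``. A fraction ``error_rate`` of responded trials is
    marked incorrect and ``miss_rate`` of trials get no response (missing
    RT). ``post_error`` flags the trial after an error within a block.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    out = trials.copy().reset_index(drop=True)
    subjects = out["subject"].unique()
    intercepts = dict(
        zip(subjects, rng.normal(0.0, config.subject_sd, len(subjects)))
    )
    mean = (
        config.rt_intercept
        + config.effect_interference * out["interference"].to_numpy()
        + config.effect_dbs * (out["dbs"] == "ON").to_numpy()
        + out["subject"].map(intercepts).to_numpy()
    )
    if np.any(mean <= 0):
        i = int(np.argmax(mean <= 0))
        raise ValueError(
            f"implied mean RT <= 0 at row {i} "
            f"(subject {out.loc[i, 'subject']}, mean {mean[i]:.1f} ms)"
        )
    k = config.rt_shape
    rt = rng.gamma(k, mean / k)
    missing = rng.random(len(out)) < config.miss_rate
    error = (~missing) & (rng.random(len(out)) < config.error_rate)
    rt[missing] = np.nan
    out["rt"] = rt
    out["correct"] = ~(missing | error)
    out["missing"] = missing

    # post-error: previous trial within the same block was an error
    out = out.sort_values(["subject", "block", "trial"]).reset_index(drop=True)
    prev_bad = (~out["correct"]).groupby(
        [out["subject"], out["block"]]
    ).shift(1, fill_value=False)
    out["post_error"] = prev_bad.to_numpy()
    return out


def simulate_trials(config: SimConfig) -> pd.DataFrame:
    """Convenience: trial table with RTs for the whole cohort."""
    return simulate_rts(make_trial_table(config), config)


# ---------------------------------------------------------------------------
# Epoched time courses
# ---------------------------------------------------------------------------

def one_over_f_noise(
    n_times: int,
    sfreq: float,
    exponent: float,
    rng: np.random.Generator,
    size=(),
) -> np.ndarray:
    """Power-law (1/f^exponent) noise via spectral shaping of white noise.

    Output has unit standard deviation along the last axis.
    """
    shape = tuple(size) + (n_times,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n=n_times, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _evoked_waveform(times: np.ndarray, config: SimConfig, interference: int) -> np.ndarray:
    """Condition-locked evoked deflection: a biphasic low-frequency wave
    starting at the digit onset, slightly larger on interference trials."""
    t0 = config.msit_onset
    dur = 0.6
    rel = (times - t0) / dur
    env = np.where((rel >= 0) & (rel <= 1), np.sin(np.pi * rel) ** 2, 0.0)
    wave = env * np.sin(2 * np.pi * 2.0 * (times - t0))
    return config.erp_amplitude * (1.0 + 0.3 * interference) * wave


def _burst(
    times: np.ndarray,
    config: SimConfig,
    amplitude: float,
    phase: float,
    center: float,
) -> np.ndarray:
    """Hanning-windowed theta burst with the given carrier phase."""
    half = config.burst_duration / 2.0
    rel = (times - center + half) / config.burst_duration
    env = np.where((rel >= 0) & (rel <= 1), 0.5 - 0.5 * np.cos(2 * np.pi * rel), 0.0)
    return amplitude * env * np.cos(2 * np.pi * config.theta_freq * (times - center) + phase)


def simulate_epochs(
    trials: pd.DataFrame,
    config: SimConfig,
    window: tuple[float, float] | None = None,
    label_names: list[str] | None = None,
    seed: int | None = None,
) -> EpochArray:
    """Stimulus-locked ROI epochs for each trial row.

    Each trial's trace per label is 1/f noise + a condition-locked evoked
    waveform (identical across trials within an interference condition) + a
    theta burst with uniformly random carrier phase whose amplitude gain is
    ``burst_amplitude · 10^((g_int·interference + g_dbs·[ON]) / 20)``.
    Random phase makes the burst cancel in trial averages, so burst power is
    induced (non-phase-locked) by construction.
    """
    window = tuple(window if window is not None else config.epoch_window)
    if window[0] > -0.5 or window[1] < config.burst_center + config.burst_duration:
        raise ValueError(
            f"epoch window {window} must cover the baseline (-0.5, -0.1) s "
            "and the post-stimulus analysis period"
        )
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    labels = list(label_names if label_names is not None else config.label_names)
    sfreq = config.sampling_rate
    n_times = int(round((window[1] - window[0]) * sfreq)) + 1
    times = window[0] + np.arange(n_times) / sfreq

    trials = trials.reset_index(drop=True)
    n_trials = len(trials)
    data = config.noise_amplitude * one_over_f_noise(
        n_times, sfreq, config.noise_exponent, rng, size=(n_trials, len(labels))
    )

    evoked = {
        i: _evoked_waveform(times, config, i) for i in (0, 1)
    }
    interf = trials["interference"].to_numpy()
    on = (trials["dbs"] == "ON").to_numpy()
    gain_db = (
        config.theta_burst_gain_interference * interf
        + config.theta_burst_gain_dbs * on
    )
    amp = config.burst_amplitude * 10.0 ** (gain_db / 20.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_trials, len(labels)))
    centers = config.burst_center + rng.uniform(-0.05, 0.05, size=n_trials)
    for t in range(n_trials):
        data[t] += evoked[int(interf[t])]
        for li in range(len(labels)):
            data[t, li] += _burst(times, config, amp[t], phases[t, li], centers[t])
    return EpochArray(data, times, sfreq, labels, "stimulus", trials.copy())


def simulate_resting(
    config: SimConfig,
    n_seconds: float,
    dbs_state: str,
    seed: int | None = None,
    theta_scale: float = 1.0,
) -> np.ndarray:
    """Continuous resting trace per label: 1/f noise + stochastic theta.

    Theta is narrowband-filtered white noise (±1.5 Hz around
    ``theta_freq``), so its power decorrelates within a fraction of a
    second and one-second epochs are exchangeable — a coherent global
    sinusoid would give every epoch of a trace nearly the same power
    estimate and break the rank test's independence assumption. ON and OFF
    are exchangeable by default (``theta_scale=1`` for both states); pass a
    different ``theta_scale`` to inject a state difference. Returns an
    array of shape (n_labels, n_times).
    """
    import scipy.signal as ss

    seed = config.seed if seed is None else seed
    state_key = 0 if dbs_state == "ON" else 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13, state_key]))
    sfreq = config.sampling_rate
    n_times = int(round(n_seconds * sfreq))
    n_labels = len(config.label_names)
    x = config.noise_amplitude * one_over_f_noise(
        n_times, sfreq, config.noise_exponent, rng, size=(n_labels,)
    )
    sos = ss.butter(
        2,
        [config.theta_freq - 1.5, config.theta_freq + 1.5],
        "bandpass",
        fs=sfreq,
        output="sos",
    )
    for li in range(n_labels):
        theta = ss.sosfiltfilt(sos, rng.standard_normal(n_times))
        theta /= theta.std()
        x[li] += theta_scale * 0.5 * config.noise_amplitude * theta
    return x


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def simulate_cohort_biomarker(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-subject biomarker table with a tunable theta/outcome linkage.

    Draws (Δtheta, MADRS improvement) from a bivariate normal with
    population correlation ``biomarker_r``; ΔRT is drawn independently of
    outcome (speeding does not predict response). Responder = ≥50% MADRS
    drop from baseline. One subject's hypomania label is left missing when
    the cohort has at least five subjects.
    """
    if config.n_subjects < 4:
        raise ValueError("need n_subjects >= 4 for the biomarker stage")
    r = config.biomarker_r
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n = config.n_subjects
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(n)

    delta_theta = 0.30 + 0.25 * z1                    # dB·s, ON−OFF
    improvement = 17.0 + 8.0 * z2                     # MADRS points gained
    baseline = np.round(rng.normal(38.0, 3.0, n)).clip(25, 50)
    madrs_change = -improvement                       # follow-up − baseline
    followup = baseline + madrs_change
    responder = (baseline - followup) >= 0.5 * baseline
    delta_rt = config.effect_dbs + 15.0 * rng.standard_normal(n)
    hypomania = rng.random(n) < 0.3

    df = pd.DataFrame(
        {
            "subject": [f"S{i + 1:02d}" for i in range(n)],
            "delta_theta": delta_theta,
            "delta_rt": delta_rt,
            "madrs_baseline": baseline,
            "madrs_followup": followup,
            "madrs_change": madrs_change,
            "responder": responder,
            "hypomania": pd.array(hypomania, dtype="boolean"),
        }
    )
    if n >= 5:
        df.loc[df.index[-1], "hypomania"] = pd.NA
    return df


def simulate_clinical_given_theta(
    delta_theta: np.ndarray,
    config: SimConfig,
    subjects: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Clinical table conditioned on measured per-subject theta changes.

    MADRS improvement is generated around a linear function of the
    standardized Δtheta so that the population correlation equals
    ``biomarker_r``; used by the end-to-end pipeline where Δtheta comes out
    of the EEG stage rather than from :func:`simulate_cohort_biomarker`.
    """
    delta_theta = np.asarray(delta_theta, dtype=float)
    n = len(delta_theta)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    r = config.biomarker_r
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    sd = delta_theta.std(ddof=1)
    z = (delta_theta - delta_theta.mean()) / (sd if sd > 0 else 1.0)
    improvement = 17.0 + 8.0 * (r * z + math.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(n))
    baseline = np.round(rng.normal(38.0, 3.0, n)).clip(25, 50)
    madrs_change = -improvement
    followup = baseline + madrs_change
    responder = (baseline - followup) >= 0.5 * baseline
    hypomania = rng.random(n) < 0.3
    df = pd.DataFrame(
        {
            "subject": subjects if subjects is not None else [f"S{i + 1:02d}" for i in range(n)],
            "delta_theta": delta_theta,
            "madrs_baseline": baseline,
            "madrs_followup": followup,
            "madrs_change": madrs_change,
            "responder": responder,
            "hypomania": pd.array(hypomania, dtype="boolean"),
        }
    )
    if n >= 5:
        df.loc[df.index[-1], "hypomania"] = pd.NA
    return df


def null_power_dataset(
    n_subjects: int,
    n_trials: int,
    n_times: int = 150,
    sfreq: float = 100.0,
    seed: int | np.random.Generator = 0,
    smooth_sd: float = 0.05,
):
    """Null single-trial power time courses for error-rate calibration.

    Emulates induced band-power time courses with no condition effect:
    temporally smoothed Gaussian noise (correlation length ``smooth_sd``
    seconds, matching the sluggishness of wavelet power) plus a per-subject
    offset, with interference/DBS labels assigned independently of the data.

    Returns (data (n, T), design metadata DataFrame, times).
    """
    rng = np.random.default_rng(seed)
    n = n_subjects * n_trials
    x = rng.standard_normal((n, n_times))
    # Gaussian temporal smoothing via FFT
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    kernel = np.exp(-2 * (np.pi * freqs * smooth_sd) ** 2)
    x = np.fft.irfft(np.fft.rfft(x, axis=1) * kernel, n=n_times, axis=1)
    x /= x.std()
    subj = np.repeat([f"S{i + 1:02d}" for i in range(n_subjects)], n_trials)
    x += rng.normal(0, 0.5, n_subjects).repeat(n_trials)[:, None]
    meta = pd.DataFrame(
        {
            "subject": subj,
            "interference": rng.integers(0, 2, n),
            "dbs": rng.choice(["ON", "OFF"], n),
            "valence": rng.uniform(1, 9, n),
            "arousal": rng.uniform(1, 9, n),
            "trial": np.tile(np.arange(1, n_trials + 1), n_subjects),
        }
    )
    times = np.arange(n_times) / sfreq
    return x, meta, times
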