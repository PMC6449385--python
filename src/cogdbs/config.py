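"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: ROI labels: cingulate (rostral/dorsal anterior, mid), dorsomedial PFC,
#: dorsolateral PFC (middle frontal gyrus), ventrolateral PFC (anterior
#: inferior frontal gyrus — the biomarker label).
DEFAULT_LABELS = ["rACC", "dACC", "mCC", "dmPFC", "DLPFC", "VLPFC"]

#: Frequency bands (Hz) used throughout the analysis.
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 15.0), "beta": (15.0, 30.0)}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults reproduce the study conditions the analysis stages are
    designed for: 14 subjects, one 144-trial block (72 control + 72
    interference) per DBS state, gamma-distributed reaction times with a
    +224 ms interference effect and a −34 ms DBS-ON effect, and ROI time
    courses built from 1/f noise, a phase-locked evoked component, and
    non-phase-locked theta bursts whose power is boosted by interference
    and by DBS ON.
    """

    seed: int = 0
    n_subjects: int = 14
    n_blocks_per_state: int = 1
    n_control: int = 72          # control trials per block
    n_interference: int = 72     # interference trials per block

    # Label time courses are generated at the analysis rate: acquisition at
    # 1450 Hz followed by the downsample-by-3 path gives 1450/3 Hz.
    sampling_rate: float = 1450.0 / 3.0

    # --- reaction-time model (ms) -------------------------------------
    rt_shape: float = 16.0         # gamma shape; CV = 1/sqrt(shape) = 0.25
    rt_intercept: float = 800.0    # mean control-trial RT, DBS OFF
    effect_interference: float = 224.0
    effect_dbs: float = -34.0      # ON − OFF; negative = speeding
    subject_sd: float = 80.0       # SD of per-subject intercepts
    error_rate: float = 0.017      # fraction of error trials injected
    miss_rate: float = 0.01        # fraction of missing-response trials

    # --- epoch model ---------------------------------------------------
    theta_freq: float = 6.0               # Hz, burst carrier
    burst_duration: float = 0.3           # s, Hanning envelope length
    burst_center: float = 0.8             # s after picture onset
    burst_amplitude: float = 10.0         # baseline burst amplitude (a.u.)
    theta_burst_gain_interference: float = 2.0   # dB boost on conflict trials
    theta_burst_gain_dbs: float = 3.0            # dB boost with DBS ON
    erp_amplitude: float = 5.0            # evoked deflection amplitude (a.u.)
    noise_exponent: float = 1.0           # 1/f^a spectral slope
    noise_amplitude: float = 10.0         # RMS of the background noise (a.u.)
    epoch_window: tuple[float, float] = (-1.5, 3.4)   # s re picture onset
    msit_onset: float = 0.4               # s: digits appear after the picture

    # --- clinical linkage ----------------------------------------------
    biomarker_r: float = 0.76   # population corr(Δtheta, MADRS improvement)

    label_names: list[str] = field(default_factory=lambda: list(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        if self.rt_shape <= 0:
            raise ValueError("rt_shape must be > 0")
        if not -1.0 <= self.biomarker_r <= 1.0:
            raise ValueError(f"biomarker_r must be in [-1, 1], got {self.biomarker_r}")
        if self.sampling_rate <= 2 * 50.0:
            raise ValueError(
                "sampling_rate must exceed twice the highest analysis "
                f"frequency (50 Hz); got {self.sampling_rate} Hz"
            )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``sim`` controls the synthetic cohort; the remaining fields control the
    analysis stages. The config (plus seed and package version) is
    serialized next to every output so a run can be reproduced exactly.
    """

    seed: int = 0
    out_dir: str = "cogdbs_run"
    sim: SimConfig = field(default_factory=SimConfig)

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    baseline: tuple[float, float] = (-0.5, -0.1)
    tfr_fmin: float = 2.0
    tfr_fmax: float = 50.0
    tfr_n_freqs: int = 25
    tfr_n_cycles: float = 3.0
    tfr_decim: int = 6            # decimate power time courses after TFR
    analysis_window: tuple[float, float] = (-0.5, 2.0)  # cluster stage, s
    n_subjects_eeg: int = 8       # subjects contributing technically
                                  # adequate task EEG

    n_perm: int = 1000
    cluster_alpha: float = 0.05
    min_cluster_duration: float = 0.05   # s
    amplitude_threshold: float = 150.0

    behavior_candidates: list[str] = field(
        default_factory=lambda: [
            "interference",
            "dbs",
            "valence",
            "arousal",
            "interference:dbs",
        ]
    )
    behavior_nuisance: list[str] = field(default_factory=lambda: ["trial"])

    n_boot: int = 1000
    make_figures: bool = True
    skip: list[str] = field(default_factory=list)

    # ----- (de)serialization ------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.bands = {k: tuple(v) for k, v in cfg.bands.items()}
        cfg.baseline = tuple(cfg.baseline)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        """Stable short hash of the configuration, for provenance stamps."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
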