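"""Epoched multi-label time-series container with HDF5 + JSON-sidecar I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class EpochArray:
    """Trials × labels × time array with aligned per-trial metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_labels, n_times)
        Label (ROI) time courses in arbitrary amplitude units.
    times : ndarray, shape (n_times,)
        Seconds relative to the lock event.
    sfreq : float
        Sampling rate in Hz.
    label_names : list of str
        ROI label identifiers, one per label axis entry.
    lock : {"stimulus", "response"}
        Event the epochs are time-locked to.
    trial_meta : DataFrame
        One row per trial, aligned with the first axis of ``data``.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    label_names: list[str]
    lock: str = "stimulus"
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_labels, n_times)")
        n_trials, n_labels, n_times = self.data.shape
        if len(self.times) != n_times:
            raise ValueError("times length does not match data")
        if len(self.label_names) != n_labels:
            raise ValueError("label_names length does not match data")
        if len(self.trial_meta) not in (0, n_trials):
            raise ValueError("trial_meta rows do not match n_trials")
        if len(self.trial_meta) == 0:
            self.trial_meta = pd.DataFrame(index=range(n_trials))

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def window(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin) & (self.times <= tmax)

    def crop(self, tmin: float, tmax: float) -> "EpochArray":
        m = self.time_mask(tmin, tmax)
        if not m.any():
            raise ValueError(f"no samples in ({tmin}, {tmax})")
        return EpochArray(
            self.data[:, :, m],
            self.times[m],
            self.sfreq,
            list(self.label_names),
            self.lock,
            self.trial_meta.copy(),
        )

    def select_trials(self, idx) -> "EpochArray":
        idx = np.asarray(idx)
        return EpochArray(
            self.data[idx],
            self.times.copy(),
            self.sfreq,
            list(self.label_names),
            self.lock,
            self.trial_meta.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "EpochArray":
        return EpochArray(
            self.data.copy(),
            self.times.copy(),
            self.sfreq,
            list(self.label_names),
            self.lock,
            self.trial_meta.copy(),
        )

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write to HDF5 with a JSON sidecar mirroring the attributes."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset(
                "label_names",
                data=np.array(self.label_names, dtype=h5py.string_dtype()),
            )
            f.attrs["sampling_rate"] = self.sfreq
            f.attrs["lock_event"] = self.lock
            f.attrs["window"] = self.window
            meta_json = self.trial_meta.to_json(orient="table")
            f.create_dataset("trial_meta", data=meta_json)
        sidecar = {
            "sampling_rate": self.sfreq,
            "lock_event": self.lock,
            "window": list(self.window),
            "n_trials": int(self.n_trials),
            "label_names": list(self.label_names),
            "trial_meta_columns": list(map(str, self.trial_meta.columns)),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochArray":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            labels = [s.decode() if isinstance(s, bytes) else s for s in f["label_names"][()]]
            sfreq = float(f.attrs["sampling_rate"])
            lock = str(f.attrs["lock_event"])
            meta_json = f["trial_meta"][()]
            if isinstance(meta_json, bytes):
                meta_json = meta_json.decode()
        meta = pd.read_json(pd.io.common.StringIO(meta_json), orient="table")
        return cls(data, times, sfreq, labels, lock, meta.reset_index(drop=True))
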