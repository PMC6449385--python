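import numpy as np
import pandas as pd
import pytest

from cogdbs.config import SimConfig
from cogdbs import simulate


@pytest.fixture
def small_config():
    """Two-subject cohort with short epochs for fast spectral tests."""
    return SimConfig(seed=7, n_subjects=2, n_control=30, n_interference=30,
                     epoch_window=(-0.7, 1.6))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trials(small_config):
    tr = simulate.simulate_trials(small_config)
    return tr[tr.correct & tr.rt.notna() & ~tr.post_error].reset_index(drop=True)


def make_flat_trials(n_per_subject: int, subjects=("A", "B"), seed: int = 0) -> pd.DataFrame:
    """Minimal balanced trial table without simulation effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        for i in range(n_per_subject):
            rows.append(
                {
                    "subject": s,
                    "block": 1 + (i % 2),
                    "dbs": "ON" if i % 2 else "OFF",
                    "trial": i + 1,
                    "interference": int(rng.integers(0, 2)),
                    "valence": float(rng.uniform(1, 9)),
                    "arousal": float(rng.uniform(1, 9)),
                    "rt": float(rng.gamma(16, 900 / 16)),
                    "correct": True,
                    "missing": False,
                    "post_error": False,
                }
            )
    return pd.DataFrame(rows)
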