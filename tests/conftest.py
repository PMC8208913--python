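"""Shared fixtures: small task designs and cached simulated subjects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from erroraware.simulate import TaskDesign, simulate_subject
from erroraware.montage import ring_montage
from erroraware import behavior as bh
from erroraware import preprocess as pp


@pytest.fixture(scope="session")
def montage61():
    return ring_montage()


@pytest.fixture(scope="session")
def small_design():
    return TaskDesign(n_trials=120, n_standard=96, n_number_target=12,
                      n_repeat_target=12)


@pytest.fixture(scope="session")
def behavior_subject():
    """One full-length behavioral session (no EEG)."""
    trials, _ = simulate_subject(seed=11, with_eeg=False)
    return bh.add_previous_trial_columns(trials)


@pytest.fixture(scope="session")
def eeg_subject():
    """One subject with error-trial EEG, filtered and baseline-corrected."""
    trials, epochs = simulate_subject(seed=5, eeg_trials="error")
    trials = bh.add_previous_trial_columns(trials)
    filtered, _ = bh.filter_trials(trials)
    epochs = pp.baseline_correct(pp.rereference_common_average(epochs))
    keep = np.isin(epochs.trial_index, filtered["trial_nr"].to_numpy())
    return filtered, epochs.select_trials(keep)


def make_error_trial_table(n: int, n_aware: int, seed: int) -> pd.DataFrame:
    """Minimal table of error trials (for decoding/ITPC unit tests)."""
    rng = np.random.default_rng(seed)
    aware = np.zeros(n, dtype=bool)
    aware[rng.choice(n, size=n_aware, replace=False)] = True
    return pd.DataFrame({
        "trial_nr": np.arange(1, n + 1),
        "number": rng.choice([40, 48, 60, 70], size=n),
        "trial_type": "standard",
        "congruency": rng.choice(["congruent", "incongruent"], size=n),
        "jitter_ms": rng.choice([300, 350, 400, 450], size=n),
        "distance": rng.integers(1, 21, size=n),
        "response": "button1",
        "rt_ms": np.exp(rng.normal(np.log(420), 0.18, size=n)),
        "accuracy": "error",
        "judgment": np.where(aware, "said_error", "said_correct"),
        "judgment_rt_ms": np.exp(rng.normal(np.log(600), 0.25, size=n)),
        "awareness": np.where(aware, "aware_error", "unaware_error"),
    })


@pytest.fixture(scope="session")
def balanced_error_table():
    return make_error_trial_table(120, 60, seed=3)
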