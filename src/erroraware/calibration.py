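"""Empirical calibration of the awareness decoder's chance level.

With balanced classes and a stratified prediction set, the decoder's
expected accuracy under label permutation is exactly 50%.  This module
measures that chance level the hard way - running the full decoding
pipeline on pure-noise EEG with permuted labels - so the pipeline's
empirical null can be compared against the theoretical 50%.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .simulate import GroundTruth, simulate_eeg
from .montage import ring_montage
from . import mvpa

__all__ = ["noise_error_epochs", "decoder_chance_calibration"]


def _balanced_error_table(n_epochs: int, rng: np.random.Generator
                          ) -> pd.DataFrame:
    n_aware = n_epochs // 2
    aware = np.zeros(n_epochs, dtype=bool)
    aware[rng.choice(n_epochs, size=n_aware, replace=False)] = True
    return pd.DataFrame({
        "trial_nr": np.arange(1, n_epochs + 1),
        "number": rng.choice([40, 48, 60, 70], size=n_epochs),
        "trial_type": "standard",
        "congruency": rng.choice(["congruent", "incongruent"],
                                 size=n_epochs),
        "jitter_ms": rng.choice([300, 350, 400, 450], size=n_epochs),
        "distance": rng.integers(1, 21, size=n_epochs),
        "response": "button1",
        "rt_ms": np.exp(rng.normal(np.log(420), 0.18, size=n_epochs)),
        "accuracy": "error",
        "judgment": np.where(aware, "said_error", "said_correct"),
        "judgment_rt_ms": np.exp(rng.normal(np.log(600), 0.25,
                                            size=n_epochs)),
        "awareness": np.where(aware, "aware_error", "unaware_error"),
    })


def noise_error_epochs(n_epochs: int, seed: int):
    """Balanced aware/unaware error trials whose EEG is pure 1/f noise."""
    rng = np.random.default_rng(seed)
    table = _balanced_error_table(n_epochs, rng)
    truth = replace(GroundTruth(), ern_base=0.0, pe_base=0.0, osc_amp=0.0,
                    seed=seed)
    epochs = simulate_eeg(table, truth, ring_montage(), seed=rng)
    labels = table["awareness"].to_numpy()
    return epochs, labels


def decoder_chance_calibration(seed: int = 0, n_subjects: int = 10,
                               n_epochs: int = 120,
                               n_replicates: int = 200,
                               n_folds: int = 8,
                               step_ms: float = 25.0) -> dict:
    """Mean held-out accuracy of the decoder under label permutation.

    ``n_replicates`` permutation replicates are spread evenly over
    ``n_subjects`` independently simulated noise subjects; each replicate
    permutes the labels and runs the full decoding pipeline (features,
    balancing, stratified folds, per-timepoint SVMs), then averages
    accuracy over timepoints.  Returns the replicate mean/SE in percent.
    """
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in ss.spawn(n_subjects)]
    cfg = mvpa.DecodingConfig(n_folds=n_folds, step_ms=step_ms, seed=seed)
    reps_per_subject = int(np.ceil(n_replicates / n_subjects))
    accs = []
    for s_seed in subject_seeds:
        epochs, labels = noise_error_epochs(n_epochs, s_seed)
        feats, _ = mvpa.prepare_features(epochs, cfg)
        rng = np.random.default_rng(s_seed + 1)
        for _ in range(reps_per_subject):
            if len(accs) >= n_replicates:
                break
            perm = rng.permutation(labels)
            res = mvpa.decode_timecourse(feats, perm, cfg, rng)
            accs.append(res.accuracy.mean())
    accs = np.asarray(accs[:n_replicates])
    return {
        "mean_accuracy_pct": float(accs.mean() * 100.0),
        "mc_se_pct": float(accs.std(ddof=1) / np.sqrt(accs.size) * 100.0),
        "n_replicates": int(accs.size),
        "replicate_accuracies": accs,
    }
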