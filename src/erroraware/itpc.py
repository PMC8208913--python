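"""Intertrial phase clustering (ITPC) and its Rayleigh-Z transform.

Time-frequency phase angles are extracted per trial with complex Morlet
wavelets (3-8 cycles log-spaced over a 2-30 Hz grid by default).  The
phase-clustering statistic is the modulus of the mean unit phasor over
trials,

    ITPC(f, t) = | n^-1 sum_r exp(i k_{f,t,r}) |,

which is 0 for uniformly scattered phases and 1 for perfect locking, and
its trial-count-corrected Rayleigh-Z transform ``ITPC_z = n * ITPC^2``
(expected value ~1 under the uniform null regardless of n).

Epochs are mirror-extended before convolution so the full window can be
analyzed; a per-frequency validity mask marks samples at least one
half-wavelet away from the true epoch edges, and contrasts restrict
themselves to valid samples at the probe frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st
from mne.time_frequency import tfr_array_morlet

from .containers import EpochSet

__all__ = ["ItpcMap", "default_freqs", "tf_phase", "compute_itpc",
           "itpc_contrast"]


def default_freqs(n: int = 20, fmin: float = 2.0, fmax: float = 30.0
                  ) -> np.ndarray:
    return np.geomspace(fmin, fmax, n)


def default_cycles(freqs: np.ndarray, cmin: float = 3.0, cmax: float = 8.0
                   ) -> np.ndarray:
    """Cycles log-spaced from ``cmin`` (lowest freq) to ``cmax`` (highest)."""
    freqs = np.asarray(freqs, float)
    if freqs.size == 1:
        return np.array([cmin])
    logf = (np.log(freqs) - np.log(freqs[0])) \
        / (np.log(freqs[-1]) - np.log(freqs[0]))
    return np.exp(np.log(cmin) + logf * (np.log(cmax) - np.log(cmin)))


def tf_phase(epochs: EpochSet, electrode: str,
             freqs: np.ndarray | None = None,
             cycles: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Morlet phase angles at one electrode.

    Returns ``(phases, freqs, times, valid)`` where phases has shape
    ``freq x time x trial`` with values in (-pi, pi], and ``valid`` is a
    ``freq x time`` mask of samples at least one wavelet half-length from
    the epoch edges (edge estimates lean on mirrored data).
    """
    freqs = default_freqs() if freqs is None else np.asarray(freqs, float)
    cycles = default_cycles(freqs) if cycles is None \
        else np.asarray(cycles, float)
    ch = epochs.channel_index(electrode)
    x = epochs.data[ch].T  # trials x time
    n_times = x.shape[1]
    half_len = np.ceil(cycles / (2.0 * freqs) * epochs.sfreq).astype(int)
    pad = min(int(half_len.max()), n_times - 1)
    # mirror-extend: [x[pad:0:-1], x, x[-2:-pad-2:-1]]
    xp = np.concatenate([x[:, pad:0:-1], x, x[:, -2:-pad - 2:-1]], axis=1)
    out = tfr_array_morlet(xp[:, None, :], sfreq=epochs.sfreq, freqs=freqs,
                           n_cycles=cycles, output="phase", zero_mean=True)
    phases = out[:, 0, :, pad:pad + n_times]  # trials x freq x time
    phases = np.transpose(phases, (1, 2, 0))
    idx = np.arange(n_times)
    valid = (idx[None, :] >= half_len[:, None]) \
        & (idx[None, :] <= n_times - 1 - half_len[:, None])
    return phases, freqs, epochs.times, valid


@dataclass
class ItpcMap:
    """ITPC over a frequency x time grid for one trial set."""

    itpc: np.ndarray
    itpc_z: np.ndarray
    n_trials: int
    freqs: np.ndarray
    times: np.ndarray
    electrode: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.nanmin(self.itpc) < -1e-12 or np.nanmax(self.itpc) > 1 + 1e-12:
            raise ValueError("ITPC must lie in [0, 1]")


def compute_itpc(phases: np.ndarray, freqs: np.ndarray | None = None,
                 times: np.ndarray | None = None, electrode: str = "",
                 valid: np.ndarray | None = None) -> ItpcMap:
    """ITPC and Rayleigh-Z from phase angles (trial axis last)."""
    phases = np.asarray(phases)
    n = phases.shape[-1]
    if n < 1:
        raise ValueError("need at least one trial")
    itpc = np.abs(np.mean(np.exp(1j * phases), axis=-1))
    return ItpcMap(itpc=itpc, itpc_z=n * itpc**2, n_trials=n,
                   freqs=np.asarray(freqs) if freqs is not None else None,
                   times=np.asarray(times) if times is not None else None,
                   electrode=electrode, valid=valid)


def itpc_contrast(aware: ItpcMap, unaware: ItpcMap,
                  regression_timecourse: np.ndarray | None = None,
                  regression_times: np.ndarray | None = None,
                  probe_freq_hz: float = 9.0) -> dict:
    """Aware - unaware phase-clustering difference, optionally correlated
    with a regression-weight time course.

    The difference is taken on the Rayleigh-Z maps (which correct for the
    unequal trial counts of the two classes).  When a group
    regression-weight time course is supplied, it is interpolated onto the
    ITPC time grid and Pearson-correlated with the Z-difference at the
    grid frequency closest to ``probe_freq_hz``, over valid samples.
    A constant difference course has no defined correlation and is
    flagged ``degenerate``.
    """
    if aware.itpc.shape != unaware.itpc.shape:
        raise ValueError("aware/unaware maps differ in shape")
    z_diff = aware.itpc_z - unaware.itpc_z
    out = {
        "z_diff": z_diff,
        "itpc_diff": aware.itpc - unaware.itpc,
        "freqs": aware.freqs, "times": aware.times,
        "n_aware": aware.n_trials, "n_unaware": unaware.n_trials,
    }
    if regression_timecourse is None:
        return out
    fi = int(np.argmin(np.abs(aware.freqs - probe_freq_hz)))
    course = z_diff[fi]
    mask = np.ones(course.size, dtype=bool) if aware.valid is None \
        else aware.valid[fi]
    reg = np.interp(aware.times, regression_times, regression_timecourse)
    x, y = reg[mask], course[mask]
    out["probe_freq_hz"] = float(aware.freqs[fi])
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        out.update(r=np.nan, p=np.nan, degenerate=True)
        return out
    r, p = st.pearsonr(x, y)
    out.update(r=float(r), p=float(p), degenerate=False)
    return out
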