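"""Core data containers shared across the pipeline.

An :class:`EpochSet` holds epoched multichannel EEG as a dense
``channels x time x trials`` voltage array (microvolts) together with the
metadata needed to interpret it: channel labels, sampling rate, the epoch
window relative to the lock event, the lock event itself (stimulus or
response onset), and a mapping back into the trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Epoched EEG: ``data[channel, time, trial]`` in microvolts."""

    data: np.ndarray
    ch_names: list[str]
    sfreq: float
    window: tuple[float, float]
    lock: str = "response"
    trial_index: np.ndarray = field(default=None)  # 1-based trial numbers

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x time x trials")
        n_ch, n_times, n_trials = self.data.shape
        if len(self.ch_names) != n_ch:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {n_ch} channels"
            )
        if self.lock not in ("stimulus", "response"):
            raise ValueError(f"unknown lock event {self.lock!r}")
        expected = int(round((self.window[1] - self.window[0]) * self.sfreq))
        if n_times != expected:
            raise ValueError(
                f"window {self.window} at {self.sfreq} Hz implies "
                f"{expected} samples, data has {n_times}"
            )
        if self.trial_index is None:
            self.trial_index = np.arange(1, n_trials + 1)
        self.trial_index = np.asarray(self.trial_index, dtype=np.int64)
        if self.trial_index.shape != (n_trials,):
            raise ValueError("trial_index length must match trial count")
        if len(np.unique(self.trial_index)) != n_trials:
            raise ValueError("trial_index contains duplicates")
        if np.any(self.trial_index < 1):
            raise ValueError("trial_index is 1-based; found values < 1")

    # -- geometry ----------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the lock event."""
        return self.window[0] + np.arange(self.n_times) / self.sfreq

    def time_to_sample(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        idx = int(round((t - self.window[0]) * self.sfreq))
        return min(max(idx, 0), self.n_times - 1)

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def select_trials(self, keep: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to ``keep`` (bool mask or positions)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self, data=self.data[:, :, keep], trial_index=self.trial_index[keep]
        )

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(),
                       trial_index=self.trial_index.copy())

    # -- persistence -------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset(
                "ch_names",
                data=np.array(self.ch_names, dtype=h5py.string_dtype()),
            )
            f.create_dataset("sfreq", data=float(self.sfreq))
            f.create_dataset("window", data=np.asarray(self.window, float))
            f.create_dataset("trial_index", data=self.trial_index)
            f.attrs["lock"] = self.lock

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()].astype(np.float64),
                ch_names=[s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["ch_names"][()]],
                sfreq=float(f["sfreq"][()]),
                window=tuple(f["window"][()]),
                lock=str(f.attrs["lock"]),
                trial_index=f["trial_index"][()],
            )
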