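"""Time-resolved decoding of error awareness from single-trial EEG.

Whole-scalp voltage patterns on error trials are used to classify whether
the participant judged the trial an error (aware) or not (unaware), with a
linear support vector machine at every timepoint of a -100..+500 ms
response-locked window.  Features are sliding-window means (+-10 ms, 10 ms
stride) that are z-scored globally and then per electrode x timepoint over
trials.  Cross-validation is a repeated random 90/10 holdout (50 folds by
default; the prediction set never falls below 10 trials); class imbalance
is removed by random subsampling to the minority class, redrawn per fold.
A searchlight repeats the analysis one electrode at a time to localize the
information, and a label-permutation test calibrates the peak accuracy
against chance (50% for balanced classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .containers import EpochSet

__all__ = [
    "DecodingConfig", "prepare_features", "decode_timecourse",
    "searchlight", "permutation_test", "DecodingResult",
]


@dataclass(frozen=True)
class DecodingConfig:
    epoch_window: tuple[float, float] = (-0.100, 0.500)
    smooth_halfwidth_ms: float = 10.0
    step_ms: float = 10.0
    n_folds: int = 50
    train_fraction: float = 0.9
    min_predict_trials: int = 10
    n_permutations: int = 2000   # 50,000 for a publication-grade null
    svm_c: float = 1.0
    zscore_order: str = "global_then_feature"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def prepare_features(epochs: EpochSet, cfg: DecodingConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window means + two-stage z-scoring.

    Returns ``(features, step_times)`` with features shaped
    ``trials x electrodes x timepoints``; each feature has mean 0 and SD 1
    over trials (constant features are zeroed).
    """
    cfg = cfg or DecodingConfig()
    half = int(round(cfg.smooth_halfwidth_ms / 1000.0 * epochs.sfreq))
    step = max(1, int(round(cfg.step_ms / 1000.0 * epochs.sfreq)))
    t0, t1 = cfg.epoch_window
    i0 = epochs.time_to_sample(t0)
    i1 = epochs.time_to_sample(t1)
    centers = np.arange(i0, i1 + 1, step)
    data = epochs.data  # ch x time x trials
    n_times = epochs.n_times
    feats = np.empty((epochs.n_trials, epochs.n_channels, centers.size))
    for j, c in enumerate(centers):
        lo, hi = max(0, c - half), min(n_times, c + half + 1)
        feats[:, :, j] = data[:, lo:hi, :].mean(axis=1).T
    step_times = epochs.times[centers]

    if cfg.zscore_order not in ("global_then_feature", "feature_then_global"):
        raise ValueError(f"unknown zscore_order {cfg.zscore_order!r}")

    def global_z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    def feature_z(x):
        mu = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, keepdims=True)
        out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return out

    if cfg.zscore_order == "global_then_feature":
        feats = feature_z(global_z(feats))
    else:
        feats = global_z(feature_z(feats))
    return feats, step_times


@dataclass
class DecodingResult:
    accuracy: np.ndarray          # per timepoint, fold-averaged
    times: np.ndarray
    peak_accuracy: float
    peak_latency_s: float
    n_folds: int
    n_per_class: int


def _balanced_split(labels: np.ndarray, cfg: DecodingConfig,
                    rng: np.random.Generator):
    """One fold: subsample to the minority class, then a stratified
    90/10 split (the prediction set keeps at least ``min_predict_trials``
    trials and equal class counts, so chance stays exactly 50%)."""
    classes = np.unique(labels)
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    n_min = min(len(ix) for ix in idx_by_class)
    n_test = max(cfg.min_predict_trials,
                 int(round((1.0 - cfg.train_fraction) * 2 * n_min)))
    k = max(1, (n_test + 1) // 2)  # per-class prediction trials
    if n_min - k < 1:
        raise ValueError("insufficient trials for a train/test split")
    train, test = [], []
    for ix in idx_by_class:
        sub = rng.choice(ix, size=n_min, replace=False)
        test.append(sub[:k])
        train.append(sub[k:])
    return np.concatenate(train), np.concatenate(test)


def decode_timecourse(features: np.ndarray, labels: np.ndarray,
                      cfg: DecodingConfig | None = None,
                      rng: np.random.Generator | None = None
                      ) -> DecodingResult:
    """Fold-averaged classification accuracy at every timepoint.

    ``features``: trials x electrodes x timepoints; ``labels``: binary
    (aware / unaware).  Fully seeded: the same data and seed give an
    identical accuracy curve.
    """
    cfg = cfg or DecodingConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("decoding needs exactly two label values")
    if counts.min() < cfg.min_predict_trials:
        raise ValueError(
            f"minority class has {counts.min()} trials "
            f"(< {cfg.min_predict_trials})")
    n_tp = features.shape[2]
    acc = np.zeros(n_tp)
    for _fold in range(cfg.n_folds):
        train, test = _balanced_split(labels, cfg, rng)
        for j in range(n_tp):
            clf = SVC(kernel="linear", C=cfg.svm_c)
            clf.fit(features[train, :, j], labels[train])
            acc[j] += np.mean(clf.predict(features[test, :, j])
                              == labels[test])
    acc /= cfg.n_folds
    peak = int(np.argmax(acc))
    return DecodingResult(accuracy=acc, times=None, peak_accuracy=acc[peak],
                          peak_latency_s=np.nan, n_folds=cfg.n_folds,
                          n_per_class=int(counts.min()))


def attach_times(result: DecodingResult, times: np.ndarray
                 ) -> DecodingResult:
    result.times = np.asarray(times)
    result.peak_latency_s = float(times[int(np.argmax(result.accuracy))])
    return result


def searchlight(features: np.ndarray, labels: np.ndarray,
                cfg: DecodingConfig | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Electrode x timepoint accuracy map: the decoder restricted to a
    single electrode at a time (same settings as the full analysis)."""
    cfg = cfg or DecodingConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    n_ch = features.shape[1]
    maps = np.zeros((n_ch, features.shape[2]))
    for c in range(n_ch):
        res = decode_timecourse(features[:, [c], :], labels, cfg, rng)
        maps[c] = res.accuracy
    return maps


def permutation_test(observed_peak: float, features: np.ndarray,
                     labels: np.ndarray, cfg: DecodingConfig | None = None,
                     n_permutations: int | None = None,
                     rng: np.random.Generator | None = None
                     ) -> tuple[float, np.ndarray]:
    """Permutation p-value for a peak decoding accuracy.

    The null redraws the whole pipeline (balancing, folds, per-timepoint
    fits) with permuted labels; ``p = (1 + #{null >= observed}) /
    (1 + n_permutations)``.
    """
    cfg = cfg or DecodingConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        null[i] = decode_timecourse(features, perm, cfg, rng).peak_accuracy
    p = (1.0 + np.sum(null >= observed_peak)) / (1.0 + n_perm)
    return p, null
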