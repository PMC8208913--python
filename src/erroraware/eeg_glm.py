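"""Mass-univariate single-trial EEG regression.

The same trial-level design is fit independently at every electrode x
timepoint of the response-locked epochs with the shared robust (IRLS
bisquare) estimator, yielding per-subject beta and t maps.  Two standard
designs are provided:

* **GLM 1** (all trials): error (-1 correct, +1 error), distance, log RT,
  congruency, log trial number - the general error-processing model whose
  error regressor traces the ERN/Pe succession.
* **GLM 2** (error trials only): error awareness (-1 unaware, +1 aware),
  confidence (log judgment RT), their interaction, plus the same
  confounds - the awareness/confidence modulation model.  Optional
  controls (trial type, jitter) can be appended.

Group inference: one-sample t-test of subject betas against zero at every
point, Benjamini-Yekutieli FDR over the full electrode x time family per
regressor, plus a Bonferroni by-regressor factor for thresholded
topographies.  Peaks are extrema of the group mean beta within a window at
a target electrode (by default the electrode with the maximal effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import EpochSet
from .robust import irls_fit

__all__ = [
    "build_eeg_design", "fit_mass_univariate", "group_stats",
    "choose_target_electrode", "extract_peak", "MassGlmResult",
    "GroupGlmResult",
]

GLM1_REGRESSORS = ("intercept", "error", "distance", "log_rt",
                   "congruency", "trial_nr")
GLM2_REGRESSORS = ("intercept", "error_awareness", "confidence",
                   "awareness_x_confidence", "distance", "log_rt",
                   "congruency", "trial_nr")


def build_eeg_design(trials: pd.DataFrame, model: int = 1,
                     controls: tuple[str, ...] = ()) -> pd.DataFrame:
    """Design matrix for EEG GLM 1 or 2, indexed by ``trial_nr``.

    GLM 2 is restricted to error trials with a valid awareness judgment.
    The printed form of GLM 1 lists the distance confound twice; it is
    included once here.
    """
    df = trials
    ok = df["rt_ms"].notna() & df["accuracy"].isin(["correct", "error"])
    if model == 2:
        ok &= df["awareness"].isin(["aware_error", "unaware_error"]) \
            & df["judgment_rt_ms"].notna()
    df = df.loc[ok]
    X = pd.DataFrame(index=df["trial_nr"].to_numpy())
    X["intercept"] = 1.0
    if model == 1:
        X["error"] = np.where(df["accuracy"] == "error", 1.0, -1.0)
    elif model == 2:
        aw = np.where(df["awareness"] == "aware_error", 1.0, -1.0)
        conf = np.log(df["judgment_rt_ms"].astype(float)).to_numpy()
        X["error_awareness"] = aw
        X["confidence"] = conf
        X["awareness_x_confidence"] = aw * (conf - conf.mean())
    else:
        raise ValueError(f"unknown EEG GLM {model}")
    X["distance"] = df["distance"].astype(float).to_numpy()
    X["log_rt"] = np.log(df["rt_ms"].astype(float)).to_numpy()
    X["congruency"] = np.where(df["congruency"] == "incongruent", 1.0, -1.0)
    X["trial_nr"] = np.log(df["trial_nr"].astype(float)).to_numpy()
    for ctl in controls:
        if ctl == "trial_type":
            X["trial_type"] = np.where(df["trial_type"] == "standard",
                                       -1.0, 1.0)
        elif ctl == "jitter":
            lv = np.sort(df["jitter_ms"].unique())
            X["jitter"] = np.where(
                df["jitter_ms"].isin(lv[: len(lv) // 2]), -1.0, 1.0)
        else:
            raise ValueError(f"unknown control regressor {ctl!r}")
    return X


@dataclass
class MassGlmResult:
    """Per-subject mass-univariate fit: arrays regressor x channel x time."""

    beta: np.ndarray
    tvalues: np.ndarray
    regressors: tuple[str, ...]
    ch_names: list[str]
    times: np.ndarray
    ok: np.ndarray          # channel x time; False = no fit at that point
    n_trials: int

    def regressor_index(self, name: str) -> int:
        return self.regressors.index(name)


def fit_mass_univariate(epochs: EpochSet, design: pd.DataFrame,
                        decim: int = 1) -> MassGlmResult:
    """Robust regression of single-trial voltage on the design everywhere.

    ``design`` rows are matched to epochs via ``trial_nr``; epochs without
    a design row (e.g. behaviorally excluded trials) are dropped, mirroring
    the rule that behavioral exclusions also leave the EEG analyses.
    ``decim`` subsamples the time axis (analysis-grid choice, not a filter).
    """
    common = np.intersect1d(design.index.to_numpy(), epochs.trial_index)
    if common.size < design.shape[1] + 2:
        raise ValueError("too few matched trials for the design")
    X = design.loc[common]
    pos = {t: i for i, t in enumerate(epochs.trial_index)}
    cols = np.array([pos[t] for t in common])
    data = epochs.data[:, ::decim, :][:, :, cols]
    n_ch, n_t, n_trials = data.shape
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("non-finite regressor values")

    Y = data.reshape(n_ch * n_t, n_trials).T  # trials x points
    fit = irls_fit(X.to_numpy(), Y)
    p = X.shape[1]
    return MassGlmResult(
        beta=fit.beta.reshape(p, n_ch, n_t),
        tvalues=fit.tvalues.reshape(p, n_ch, n_t),
        regressors=tuple(X.columns),
        ch_names=list(epochs.ch_names),
        times=epochs.times[::decim],
        ok=fit.ok.reshape(n_ch, n_t),
        n_trials=n_trials,
    )


@dataclass
class GroupGlmResult:
    """Group statistics over subjects at every electrode x timepoint."""

    b: np.ndarray               # group mean beta, regressor x ch x time
    t: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray        # BY-FDR significant, same shape
    bonferroni_mask: np.ndarray  # p * n_regressors < alpha
    ci99: np.ndarray            # regressor x ch x time x 2
    regressors: tuple[str, ...]
    ch_names: list[str]
    times: np.ndarray
    n_subjects: int
    q: float
    degenerate: np.ndarray      # zero between-subject variance points

    def regressor_index(self, name: str) -> int:
        return self.regressors.index(name)


def group_stats(results: list[MassGlmResult], q: float = 0.05,
                alpha: float = 0.05) -> GroupGlmResult:
    """One-sample t over subjects per point; BY-FDR per regressor family.

    The FDR family is all timepoints x electrodes of one regressor
    (full-scalp topographies are reported).  A per-regressor Bonferroni
    mask (``p * n_regressors < alpha``) is provided for thresholded
    topography displays.  Points where every subject contributed an
    identical beta have undefined t and are flagged degenerate.
    """
    first = results[0]
    betas = np.stack([r.beta for r in results])  # subj x reg x ch x t
    ok = np.stack([r.ok for r in results]).all(axis=0)
    n_sub = betas.shape[0]
    if n_sub < 2:
        raise ValueError("group statistics need >= 2 subjects")
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n_sub))
    p = 2.0 * st.t.sf(np.abs(t), df=n_sub - 1)
    p = np.where(degenerate | ~ok[None], np.nan, p)
    t = np.where(degenerate | ~ok[None], np.nan, t)

    n_reg = mean.shape[0]
    fdr_mask = np.zeros_like(p, dtype=bool)
    for r in range(n_reg):
        pr = p[r].ravel()
        tested = np.isfinite(pr)
        if tested.any():
            rej = np.zeros_like(pr, dtype=bool)
            rej[tested] = multipletests(pr[tested], alpha=q,
                                        method="fdr_by")[0]
            fdr_mask[r] = rej.reshape(p[r].shape)
    with np.errstate(invalid="ignore"):
        bonf_mask = (p * n_reg) < alpha
    half = st.t.ppf(0.995, n_sub - 1) * sd / np.sqrt(n_sub)
    ci99 = np.stack([mean - half, mean + half], axis=-1)
    return GroupGlmResult(
        b=mean, t=t, p=p, fdr_mask=fdr_mask,
        bonferroni_mask=np.where(np.isnan(p), False, bonf_mask),
        ci99=ci99, regressors=first.regressors, ch_names=first.ch_names,
        times=first.times, n_subjects=n_sub, q=q, degenerate=degenerate,
    )


def choose_target_electrode(group: GroupGlmResult, regressor: str = "error"
                            ) -> str:
    """Electrode with the maximal absolute group effect of ``regressor``
    (the conventional way to pick the target site from GLM 1)."""
    r = group.regressor_index(regressor)
    score = np.nanmax(np.abs(group.b[r]), axis=1)
    return group.ch_names[int(np.argmax(score))]


def extract_peak(group: GroupGlmResult, regressor: str,
                 window: tuple[float, float], electrode: str | None = None,
                 polarity: str = "abs") -> dict:
    """Peak of the group regression weight within a latency window.

    ``polarity``: ``'neg'``/``'pos'`` select the signed extremum, ``'abs'``
    the largest magnitude.  Exact ties resolve to the earliest latency and
    are reported in the ``tied`` field.
    """
    r = group.regressor_index(regressor)
    if electrode is None:
        electrode = choose_target_electrode(group, regressor)
    ch = group.ch_names.index(electrode)
    tmask = (group.times >= window[0]) & (group.times <= window[1])
    course = group.b[r, ch, tmask]
    times = group.times[tmask]
    if course.size == 0 or not np.any(np.isfinite(course)):
        raise ValueError("no finite group betas inside the window")
    score = {"neg": -course, "pos": course, "abs": np.abs(course)}[polarity]
    best = np.nanmax(score)
    hits = np.flatnonzero(score == best)
    i = hits[0]  # earliest-latency tie-break
    n_reg = len(group.regressors)
    p = group.p[r, ch, tmask][i]
    return {
        "regressor": regressor, "electrode": electrode,
        "latency_s": float(times[i]), "b": float(course[i]),
        "ci99": (float(group.ci99[r, ch, tmask, 0][i]),
                 float(group.ci99[r, ch, tmask, 1][i])),
        "p_corrected": float(min(1.0, p * n_reg)) if np.isfinite(p)
        else np.nan,
        "significant_fdr": bool(group.fdr_mask[r, ch, tmask][i]),
        "tied": int(hits.size - 1),
    }
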