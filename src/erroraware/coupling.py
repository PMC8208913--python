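"""Coupling between error-related EEG activity and post-error adjustments.

Two complementary analyses:

* **Single-trial**: next-trial log RT is regressed on the error trial's
  EEG voltage at every electrode x timepoint (robust IRLS), controlling
  for the accuracy-judgment RT and the next trial's type, congruency and
  jitter - separately for aware and unaware errors.  Because the voltage
  regressor varies with the point being fit, the design matrix is built
  per point.

* **Group**: across subjects, the awareness-regressor weights at the
  ERN and Pe peaks (fixed group-level latency/electrode, which avoids
  per-subject peak-selection bias) are Pearson-correlated with the
  subjects' aware-error post-error-slowing weights.  Sign convention: the
  ERN is a negative deflection, so a "larger ERN" is a more negative
  regression weight; stronger ERN-PES coupling therefore shows up as a
  *negative* correlation between ERN awareness weights and PES weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import EpochSet
from .robust import irls_fit

__all__ = ["eeg_to_next_rt", "group_ern_pes_correlation",
           "NextRtCouplingResult"]


@dataclass
class NextRtCouplingResult:
    """Voltage-regressor betas/t for next-trial RT: channel x time."""

    beta: np.ndarray
    tvalues: np.ndarray
    ch_names: list[str]
    times: np.ndarray
    n_trials: int
    controls: tuple[str, ...]


def _next_trial_design(trials: pd.DataFrame, awareness: str) -> pd.DataFrame:
    """Controls + response for error trials with a usable following trial."""
    df = trials.sort_values("trial_nr").reset_index(drop=True)
    nxt = df.shift(-1)
    consecutive = nxt["trial_nr"] == df["trial_nr"] + 1
    ok = (df["awareness"] == f"{awareness}_error") & consecutive \
        & df["judgment_rt_ms"].notna() & nxt["rt_ms"].notna()
    sel = df.loc[ok]
    nxt = nxt.loc[ok]
    lv = np.sort(trials["jitter_ms"].dropna().unique())
    X = pd.DataFrame(index=sel["trial_nr"].to_numpy())
    X["intercept"] = 1.0
    X["judgment_rt"] = np.log(sel["judgment_rt_ms"].astype(float)).to_numpy()
    X["next_trial_type"] = np.where(nxt["trial_type"] == "standard",
                                    -1.0, 1.0)
    X["next_congruency"] = np.where(nxt["congruency"] == "incongruent",
                                    1.0, -1.0)
    X["next_jitter"] = np.where(nxt["jitter_ms"].isin(lv[: len(lv) // 2]),
                                -1.0, 1.0)
    X["__y__"] = np.log(nxt["rt_ms"].astype(float)).to_numpy()
    return X


def eeg_to_next_rt(epochs: EpochSet, trials: pd.DataFrame,
                   awareness: str = "aware", electrode: str | None = None,
                   decim: int = 1) -> NextRtCouplingResult:
    """Robust regression of next-trial log RT on error-trial voltage.

    ``electrode`` restricts the map to one channel (e.g. ``"Cz"``);
    ``decim`` subsamples the time axis.  The voltage column is the second
    regressor of a per-point design; its beta/t maps are returned.
    """
    X = _next_trial_design(trials, awareness)
    y = X.pop("__y__")
    common = np.intersect1d(X.index.to_numpy(), epochs.trial_index)
    if common.size < X.shape[1] + 4:
        raise ValueError("too few error trials with a following trial")
    X = X.loc[common]
    y = y.loc[common].to_numpy()
    pos = {t: i for i, t in enumerate(epochs.trial_index)}
    cols = np.array([pos[t] for t in common])

    chans = range(epochs.n_channels) if electrode is None \
        else [epochs.channel_index(electrode)]
    chans = list(chans)
    data = epochs.data[:, ::decim, :][:, :, cols]
    n_t = data.shape[1]
    n = common.size
    controls = X.to_numpy()  # n x (1 + n_controls)
    p = controls.shape[1] + 1
    m = len(chans) * n_t
    X3 = np.empty((m, n, p))
    X3[:, :, 0] = controls[:, 0]
    X3[:, :, 2:] = controls[None, :, 1:]
    volt = data[chans].reshape(m, n)
    X3[:, :, 1] = volt
    fit = irls_fit(X3, np.repeat(y[:, None], m, axis=1))
    beta = fit.beta[1].reshape(len(chans), n_t)
    tval = fit.tvalues[1].reshape(len(chans), n_t)
    return NextRtCouplingResult(
        beta=beta, tvalues=tval,
        ch_names=[epochs.ch_names[c] for c in chans],
        times=epochs.times[::decim], n_trials=n,
        controls=tuple(c for c in X.columns if c != "intercept"))


def group_ern_pes_correlation(component_betas: np.ndarray,
                              pes_betas: np.ndarray) -> dict:
    """Pearson correlation across subjects between a component's
    awareness-regressor peak weights and the aware-error PES weights."""
    x = np.asarray(component_betas, float)
    y = np.asarray(pes_betas, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("correlation needs >= 3 subjects with both values")
    r, p = st.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(n),
            "scatter": pd.DataFrame({"component_beta": x, "pes_beta": y})}
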