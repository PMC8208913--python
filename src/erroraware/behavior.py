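"""Single-trial behavioral GLMs and post-error contrasts.

The RT model regresses natural-log RT on coded task factors with a robust
(IRLS bisquare) linear fit; the accuracy model is a logistic regression
that additionally includes log RT (speed-accuracy trade-off).  Regressor
coding follows the task conventions:

* trial type: -1 standard, +1 target
* congruency: -1 congruent, +1 incongruent
* jitter: -1 short (300/350 ms), +1 long (400/450 ms)
* distance: |number - 55| (>= 1, used in raw units)
* confidence: log previous-trial judgment RT
* trial_nr: log current trial number
* prev_accuracy (post-error models): -1 previous correct, +1 previous error

Post-error adjustments are read from the previous-accuracy extension:
post-error slowing (PES) from the prev_accuracy main effect in the RT
model, post-error change of interference (PERI) from prev_accuracy x
congruency, and post-error accuracy change (PIA) from prev_accuracy in the
accuracy model.  The *aware* variant keeps trials following correct
responses or aware errors; the *unaware* variant trials following correct
responses or unaware errors.

Group-level inference tests each regressor's per-subject t-values against
zero with a two-sided one-sample t-test, Bonferroni-corrected by the
number of regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .robust import irls_fit

__all__ = [
    "filter_trials", "add_previous_trial_columns", "build_design",
    "fit_rt_glm", "fit_accuracy_glm", "fit_group", "group_test",
    "BehavGlmResult", "SubjectFit",
]

INVALID_RESPONSES = ("miss", "multiple")
MIN_RT_MS = 80.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_trials(trials: pd.DataFrame, min_trials: int = 20
                  ) -> tuple[pd.DataFrame, dict]:
    """Apply the three behavioral exclusion rules.

    Removes (1) trials with RT < 80 ms; (2) trials with invalid responses
    (misses, multiple presses) and the trials immediately following them;
    (3) trials with invalid accuracy judgments and the trials immediately
    following them.  Adjacency is judged on the original ``trial_nr``.
    """
    df = trials
    nr = df["trial_nr"].to_numpy()
    fast = (df["rt_ms"] < MIN_RT_MS).fillna(False).to_numpy()
    invalid_resp = df["response"].isin(INVALID_RESPONSES).to_numpy()
    invalid_judg = (df["judgment"] == "invalid").to_numpy() & ~invalid_resp

    def following(mask: np.ndarray) -> np.ndarray:
        bad_next = set(nr[mask] + 1)
        return np.isin(nr, list(bad_next))

    removed = (fast | invalid_resp | following(invalid_resp)
               | invalid_judg | following(invalid_judg))
    out = df.loc[~removed]
    log = {
        "n_input": len(df),
        "n_fast_rt": int(fast.sum()),
        "n_invalid_response": int((invalid_resp | following(invalid_resp))
                                  .sum()),
        "n_invalid_judgment": int((invalid_judg | following(invalid_judg))
                                  .sum()),
        "n_removed": int(removed.sum()),
        "n_kept": len(out),
    }
    if len(out) < min_trials:
        raise ValueError(
            f"only {len(out)} trials survive filtering (< {min_trials})")
    return out, log


def add_previous_trial_columns(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach previous-trial carry-over columns (computed on the raw,
    unfiltered session so that filtering does not shift adjacency)."""
    df = trials.sort_values("trial_nr").copy()
    df["prev_judgment_rt_ms"] = df["judgment_rt_ms"].shift(1)
    df["prev_accuracy"] = df["accuracy"].shift(1)
    df["prev_awareness"] = df["awareness"].shift(1)
    return df


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _short_jitters(values: np.ndarray) -> np.ndarray:
    levels = np.unique(values)
    return np.isin(values, levels[: len(levels) // 2])


def build_design(trials: pd.DataFrame, model: str = "rt",
                 posterror: str = "none") -> pd.DataFrame:
    """Regressor matrix plus response column for one subject.

    Rows lacking a defined regressor (first trial's confidence, missing
    previous accuracy for post-error models) are dropped.  For
    ``posterror='aware'``/``'unaware'`` only trials following correct
    responses or the selected error class are retained.
    """
    if posterror not in ("none", "aware", "unaware"):
        raise ValueError(f"unknown posterror variant {posterror!r}")
    df = trials
    if "prev_judgment_rt_ms" not in df.columns:
        df = add_previous_trial_columns(df)
    keep = df["prev_judgment_rt_ms"].notna() & df["rt_ms"].notna() \
        & df["accuracy"].isin(["correct", "error"])
    if posterror != "none":
        prev_ok = df["prev_accuracy"].eq("correct") | (
            df["prev_awareness"] == f"{posterror}_error")
        keep &= df["prev_accuracy"].isin(["correct", "error"]) & prev_ok
    df = df.loc[keep]

    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["trial_type"] = np.where(df["trial_type"] == "standard", -1.0, 1.0)
    X["congruency"] = np.where(df["congruency"] == "incongruent", 1.0, -1.0)
    X["jitter"] = np.where(_short_jitters(df["jitter_ms"].to_numpy()),
                           -1.0, 1.0)
    X["distance"] = df["distance"].astype(float)
    X["confidence"] = np.log(df["prev_judgment_rt_ms"].astype(float))
    X["trial_nr"] = np.log(df["trial_nr"].astype(float))
    if posterror != "none":
        pa = np.where(df["prev_accuracy"] == "error", 1.0, -1.0)
        X["prev_accuracy"] = pa
        X["prev_accuracy_x_congruency"] = pa * X["congruency"]
        X["prev_accuracy_x_jitter"] = pa * X["jitter"]
        X["prev_accuracy_x_distance"] = pa * X["distance"]
    if model == "rt":
        X["__y__"] = np.log(df["rt_ms"].astype(float))
    elif model == "accuracy":
        X["log_rt"] = np.log(df["rt_ms"].astype(float))
        X["__y__"] = (df["accuracy"] == "correct").astype(float)
    else:
        raise ValueError(f"unknown model {model!r}")
    return X


# ---------------------------------------------------------------------------
# per-subject fits
# ---------------------------------------------------------------------------

@dataclass
class SubjectFit:
    betas: pd.Series
    tvalues: pd.Series
    ok: bool
    reason: str
    n_trials: int


def _check_design(X: pd.DataFrame) -> str:
    for col in X.columns:
        if col == "intercept":
            continue
        if X[col].nunique() < 2:
            return f"regressor {col} has a single value"
    return ""


def fit_rt_glm(trials: pd.DataFrame, posterror: str = "none") -> SubjectFit:
    """Robust regression of log RT on the coded regressors (one subject).

    Both current-correct and current-error trials enter the model.  A
    subject has "no model fit" when the IRLS does not converge or the
    design is rank deficient; callers exclude (and count) such subjects.
    """
    X = build_design(trials, model="rt", posterror=posterror)
    y = X.pop("__y__").to_numpy()
    names = list(X.columns)
    reason = _check_design(X)
    if reason:
        nan = pd.Series(np.nan, index=names)
        return SubjectFit(nan, nan.copy(), False, reason, len(X))
    fit = irls_fit(X.to_numpy(), y)
    ok = bool(fit.ok)
    return SubjectFit(pd.Series(fit.beta, index=names),
                      pd.Series(fit.tvalues, index=names), ok,
                      "" if ok else "no model fit (IRLS)", len(X))


def fit_accuracy_glm(trials: pd.DataFrame, posterror: str = "none"
                     ) -> SubjectFit:
    """Logistic regression of accuracy, including the log-RT regressor.

    Complete separation or non-convergence flags the subject as having no
    model fit.  A negative previous-accuracy beta (on the -1/+1 coding)
    indicates a post-error accuracy drop, a positive one an improvement.
    """
    X = build_design(trials, model="accuracy", posterror=posterror)
    y = X.pop("__y__").to_numpy()
    names = list(X.columns)
    nan = pd.Series(np.nan, index=names)
    reason = _check_design(X)
    if y.min() == y.max():
        reason = reason or "outcome has a single value"
    if reason:
        return SubjectFit(nan, nan.copy(), False, reason, len(X))
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        bad = (not res.mle_retvals.get("converged", True)
               or not np.all(np.isfinite(params))
               or not np.all(np.isfinite(bse))
               or np.any(np.abs(params) > 1e3))
        if bad:
            return SubjectFit(nan, nan.copy(), False,
                              "separation or non-convergence", len(X))
        return SubjectFit(pd.Series(params, index=names),
                          pd.Series(params / bse, index=names), True, "",
                          len(X))
    except Exception as exc:  # perfect separation raises in statsmodels
        return SubjectFit(nan, nan.copy(), False, f"no model fit: {exc}",
                          len(X))


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

@dataclass
class BehavGlmResult:
    subject_betas: pd.DataFrame     # subjects x regressors
    subject_tvalues: pd.DataFrame
    group: pd.DataFrame             # per-regressor group statistics
    n_subjects_fit: int
    excluded_subjects: list


def group_test(subject_values: pd.DataFrame, alpha: float = 0.05
               ) -> pd.DataFrame:
    """Two-sided one-sample t-test of per-subject values against zero,
    per regressor, Bonferroni corrected by the regressor count.

    Zero between-subject variance makes the t statistic undefined; such
    regressors are flagged ``degenerate`` instead of being reported.
    """
    k = subject_values.shape[1]
    rows = []
    for name in subject_values.columns:
        vals = subject_values[name].dropna().to_numpy()
        n = len(vals)
        mean = vals.mean() if n else np.nan
        sd = vals.std(ddof=1) if n > 1 else np.nan
        degenerate = n < 2 or not np.isfinite(sd) or sd == 0.0
        if degenerate:
            t = p = ci_lo = ci_hi = np.nan
        else:
            t, p = st.ttest_1samp(vals, 0.0)
            half = st.t.ppf(0.995, n - 1) * sd / np.sqrt(n)
            ci_lo, ci_hi = mean - half, mean + half
        rows.append({
            "regressor": name, "n": n, "mean": mean, "t": t, "p": p,
            "p_corrected": min(1.0, p * k) if np.isfinite(p) else np.nan,
            "ci99_low": ci_lo, "ci99_high": ci_hi,
            "significant": bool(np.isfinite(p) and p * k < alpha),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows).set_index("regressor")


def fit_group(subject_tables: list[pd.DataFrame], model: str = "rt",
              posterror: str = "none", alpha: float = 0.05,
              aggregate: str = "t") -> BehavGlmResult:
    """Fit one subject model per table and run the group test.

    ``aggregate='t'`` tests subject t-values (the reporting convention for
    this task); ``'beta'`` tests subject betas.
    """
    fitter = fit_rt_glm if model == "rt" else fit_accuracy_glm
    fits, excluded = [], []
    for i, tbl in enumerate(subject_tables):
        f = fitter(tbl, posterror=posterror)
        if f.ok:
            fits.append((i, f))
        else:
            excluded.append((i, f.reason))
    if not fits:
        raise ValueError("no subject produced a model fit")
    betas = pd.DataFrame({i: f.betas for i, f in fits}).T
    tvals = pd.DataFrame({i: f.tvalues for i, f in fits}).T
    group = group_test(tvals if aggregate == "t" else betas, alpha=alpha)
    return BehavGlmResult(betas, tvals, group, len(fits), excluded)
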