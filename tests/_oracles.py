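"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized implementations: the
IRLS oracle is a plain per-point loop, and the phase oracle uses direct
quadrature demodulation instead of wavelet convolution.
"""

from __future__ import annotations

import numpy as np

MAD_NORM = 0.6745


def irls_reference(X: np.ndarray, y: np.ndarray, c: float = 4.685,
                   tol: float = 1e-8, max_iter: int = 200,
                   return_converged: bool = False):
    """Loop-based bisquare IRLS for a single response vector.

    With ``return_converged`` also reports whether the iteration reached
    the tolerance (bisquare IRLS can cycle on adversarial draws; such
    fits count as "no model fit" and carry no defined estimate).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    yscale = max(np.max(np.abs(y)), 1.0)
    converged = False
    for _ in range(max_iter):
        r = y - X @ beta
        med = np.median(r)
        scale = np.median(np.abs(r - med)) / MAD_NORM
        if scale <= 1e-12 * yscale:
            w = np.ones(n)
        else:
            u = r / (c * scale)
            w = (1.0 - u**2) ** 2
            w[np.abs(u) >= 1.0] = 0.0
            if w.sum() <= p:
                w = np.ones(n)
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * y)
        new = np.linalg.solve(A, b)
        if np.max(np.abs(new - beta)) <= tol * (1.0 + np.max(np.abs(new))):
            beta = new
            converged = True
            break
        beta = new
    return (beta, converged) if return_converged else beta


def quadrature_phase(x: np.ndarray, sfreq: float, freq: float,
                     cycles: float) -> np.ndarray:
    """Phase of a signal at one frequency by windowed quadrature
    demodulation (Gaussian window matched to a Morlet of ``cycles``)."""
    x = np.asarray(x, float)
    n = x.size
    t = np.arange(n) / sfreq
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * sfreq))
    phases = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = x[lo:hi]
        tt = t[lo:hi] - t[i]
        win = np.exp(-(tt**2) / (2 * sigma_t**2))
        osc = np.exp(-2j * np.pi * freq * tt)
        z = np.sum(seg * win * osc)
        phases[i] = np.angle(z)
    return phases


def apply_filter_rules(trials) -> np.ndarray:
    """Row-by-row reapplication of the three behavioral exclusion rules.

    Returns a boolean keep-mask aligned to the (trial_nr-sorted) table.
    """
    df = trials.sort_values("trial_nr").reset_index(drop=True)
    n = len(df)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        row = df.iloc[i]
        if np.isfinite(row["rt_ms"]) and row["rt_ms"] < 80:
            keep[i] = False
        if row["response"] in ("miss", "multiple"):
            keep[i] = False
            if i + 1 < n and df.iloc[i + 1]["trial_nr"] == row["trial_nr"] + 1:
                keep[i + 1] = False
    for i in range(n):
        row = df.iloc[i]
        if row["judgment"] == "invalid" and row["response"] not in (
                "miss", "multiple"):
            keep[i] = False
            if i + 1 < n and df.iloc[i + 1]["trial_nr"] == row["trial_nr"] + 1:
                keep[i + 1] = False
    return keep
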