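"""Robust linear regression by iteratively reweighted least squares.

Single-trial EEG regression fits the same trial-level design at every
electrode x timepoint, i.e. tens of thousands of small robust regressions
sharing one design matrix.  The estimator here is therefore vectorized over
an arbitrary number of response vectors: one weighted least-squares solve
per IRLS iteration, batched with einsum.

Estimator (fixed; mirrored by the brute-force oracle in the test suite):

* Tukey bisquare psi-weights, tuning constant ``c = 4.685`` (95% Gaussian
  efficiency).
* Scale re-estimated each iteration as the median absolute deviation of the
  residuals about their median, divided by 0.6745.
* Start from ordinary least squares; iterate until the largest coefficient
  change falls below ``tol * (1 + max|beta|)`` or ``max_iter`` is reached.
* Exact (noiseless) fits - residual scale numerically zero - keep unit
  weights, so the estimate collapses to OLS.

Approximate t-values use the weighted-LS covariance
``sigma^2 (X' W X)^-1`` with ``sigma^2 = sum(w r^2) / (sum(w) - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RobustFit", "irls_fit", "BISQUARE_C"]

BISQUARE_C = 4.685
_MAD_NORM = 0.6745  # MAD of a standard normal


@dataclass
class RobustFit:
    """Fit for ``m`` response vectors against a ``p``-column design.

    beta, tvalues: ``(p, m)``; converged / rank_ok: ``(m,)`` bool.
    A point "has no model fit" when ``ok`` is False there.
    """

    beta: np.ndarray
    tvalues: np.ndarray
    converged: np.ndarray
    rank_ok: np.ndarray
    n_iter: int

    @property
    def ok(self) -> np.ndarray:
        return self.converged & self.rank_ok

    def squeeze(self) -> "RobustFit":
        """View for a single response vector (drop the point axis)."""
        return RobustFit(self.beta[:, 0], self.tvalues[:, 0],
                         self.converged[0], self.rank_ok[0], self.n_iter)


def bisquare_weights(u: np.ndarray) -> np.ndarray:
    """Tukey bisquare weights for standardized residuals ``u = r/(c*s)``."""
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


def irls_fit(X: np.ndarray, Y: np.ndarray, *, c: float = BISQUARE_C,
             tol: float = 1e-8, max_iter: int = 200) -> RobustFit:
    """Robust regression of each column of ``Y`` on ``X``.

    Parameters
    ----------
    X : (n, p) shared design, or (m, n, p) one design per response point
        (used when a regressor - e.g. single-trial voltage - varies with
        the point being fit).
    Y : (n,) or (n, m) responses.
    """
    Y = np.asarray(Y, dtype=np.float64)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    n, m = Y.shape
    X = np.asarray(X, dtype=np.float64)
    shared = X.ndim == 2
    if shared:
        p = X.shape[1]
        if X.shape[0] != n:
            raise ValueError("X and Y disagree on number of observations")
    else:
        if X.shape[0] != m or X.shape[1] != n:
            raise ValueError("per-point X must have shape (m, n, p)")
        p = X.shape[2]
    if n <= p:
        raise ValueError(f"need more observations ({n}) than regressors ({p})")

    Ym = Y.T  # (m, n)
    if shared:
        rank_ok = np.repeat(np.linalg.matrix_rank(X) == p, m)
        beta = np.linalg.lstsq(X, Y, rcond=None)[0].T  # (m, p)
        xo = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    else:
        rank_ok = np.array([np.linalg.matrix_rank(Xi) == p for Xi in X])
        beta = np.stack([
            np.linalg.lstsq(X[j], Ym[j], rcond=None)[0] for j in range(m)
        ])

    yscale = np.maximum(np.max(np.abs(Ym), axis=1), 1.0)

    def weights_for(idx, b):
        """Bisquare weights at coefficients ``b`` for points ``idx``."""
        Ya = Ym[idx]
        if shared:
            resid = Ya - b @ X.T
        else:
            resid = Ya - np.einsum("jnp,jp->jn", X[idx], b)
        med = np.median(resid, axis=1, keepdims=True)
        scale = np.median(np.abs(resid - med), axis=1) / _MAD_NORM
        exact = scale <= 1e-12 * yscale[idx]  # noiseless: keep OLS weights
        u = resid / (c * np.where(exact, 1.0, scale)[:, None])
        w = bisquare_weights(u)
        w[exact] = 1.0
        # guard: a point whose weights cannot support the fit is left as-is
        w[w.sum(axis=1) <= p] = 1.0
        return w, resid, exact

    def solve(idx, w):
        Ya = Ym[idx]
        if shared:
            A = (w @ xo).reshape(-1, p, p)
            b = (w * Ya) @ X
        else:
            Xa = X[idx]
            A = np.einsum("mni,mnj,mn->mij", Xa, Xa, w, optimize=True)
            b = np.einsum("mni,mn->mi", Xa, w * Ya, optimize=True)
        try:
            return A, np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A = A + 1e-12 * np.eye(p)
            return A, np.linalg.solve(A, b[..., None])[..., 0]

    converged = np.zeros(m, dtype=bool)
    active = np.arange(m)  # converged points freeze and leave the loop
    it = 0
    for it in range(1, max_iter + 1):
        w, _, exact = weights_for(active, beta[active])
        _, new_beta = solve(active, w)
        delta = np.max(np.abs(new_beta - beta[active]), axis=1)
        limit = tol * (1.0 + np.max(np.abs(new_beta), axis=1))
        done = (delta <= limit) | exact
        beta[active] = new_beta
        converged[active] |= done
        active = active[~done]
        if active.size == 0:
            break

    # approximate t-values from weights at the final coefficients
    all_idx = np.arange(m)
    w, resid, _ = weights_for(all_idx, beta)
    dof = np.maximum(w.sum(axis=1) - p, 1e-12)
    sigma2 = np.sum(w * resid**2, axis=1) / dof
    if shared:
        A = (w @ xo).reshape(m, p, p)
    else:
        A = np.einsum("mni,mnj,mn->mij", X, X, w, optimize=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        try:
            cov = np.linalg.inv(A) * sigma2[:, None, None]
            se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
        except np.linalg.LinAlgError:
            se = np.full((m, p), np.nan)
        tvals = np.where(se > 0, beta / se, np.nan)

    beta = beta.T.copy()
    tvals = tvals.T.copy()
    beta[:, ~rank_ok] = np.nan
    tvals[:, ~rank_ok] = np.nan
    fit = RobustFit(beta=beta, tvalues=tvals, converged=converged,
                    rank_ok=rank_ok, n_iter=it)
    return fit.squeeze() if single else fit
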