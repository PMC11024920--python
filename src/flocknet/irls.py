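"""Vectorized GLM refits for permutation nulls.

Permutation inference refits the same design matrix against thousands of
permuted responses. Refitting column-by-column through a full GLM stack
dominates runtime, so the binomial-logit refits are done here with a
batched Newton/IRLS solver that shares the design matrix across all
permutations; Gaussian refits reduce to one least-squares solve. The
solver is validated against the primary GLM fit in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["batched_logit_irls", "batched_ols"]

_CLIP = 1e-10


def batched_logit_irls(x: np.ndarray, successes: np.ndarray,
                       totals: np.ndarray, beta0: np.ndarray | None = None,
                       tol: float = 1e-8, max_iter: int = 50):
    """Fit binomial-logit GLMs for many response columns at once.

    Parameters
    ----------
    x : (n, p) design matrix shared by all fits.
    successes, totals : (n, b) success counts and trial totals, one
        column per fit.
    beta0 : optional (p,) warm start (e.g. the observed-data estimate).

    Returns
    -------
    beta : (b, p) coefficient estimates.
    usable : (b,) bool, estimates finite (numerically sound). A fit that
        drifts to very large coefficients — (quasi-)separation in the
        permuted data, where the MLE is at infinity — is still usable:
        its statistic legitimately lands in the far tail of the null.
    converged : (b,) bool, relative coefficient change below ``tol``
        within ``max_iter`` iterations.
    """
    x = np.asarray(x, float)
    y = np.asarray(successes, float)
    m = np.asarray(totals, float)
    n, p = x.shape
    b = y.shape[1]
    beta = np.tile(beta0 if beta0 is not None else np.zeros(p), (b, 1)).astype(float)
    converged = np.zeros(b, dtype=bool)
    failed = np.zeros(b, dtype=bool)
    active = np.ones(b, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = np.clip(x @ beta[idx].T, -35.0, 35.0)      # (n, k)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(m[:, idx] * mu * (1.0 - mu), _CLIP, None)
        z = eta + (y[:, idx] - m[:, idx] * mu) / w
        xtwx = np.einsum("np,nk,nq->kpq", x, w, x, optimize=True)
        xtwz = np.einsum("np,nk->kp", x, w * z, optimize=True)
        try:
            new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.stack([np.linalg.lstsq(a, v, rcond=None)[0]
                            for a, v in zip(xtwx, xtwz)])
        bad = ~np.isfinite(new).all(axis=1)
        failed[idx[bad]] = True
        active[idx[bad]] = False
        good = ~bad
        delta = np.max(np.abs(new[good] - beta[idx[good]]), axis=1)
        scale = 1.0 + np.max(np.abs(new[good]), axis=1)
        beta[idx[good]] = new[good]
        done = delta < tol * scale
        converged[idx[good][done]] = True
        active[idx[good][done]] = False
    usable = ~failed & np.isfinite(beta).all(axis=1)
    return beta, usable, converged


def batched_ols(x: np.ndarray, y: np.ndarray):
    """OLS coefficients for many response columns: (b, p) array."""
    coef, *_ = np.linalg.lstsq(np.asarray(x, float), np.asarray(y, float),
                               rcond=None)
    return coef.T
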