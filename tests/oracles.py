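"""Independent reference implementations used only as test oracles.

These are written directly from the textbook definitions of the algorithms
and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def simpls_pls1(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Regression vector of a univariate-response PLS model via SIMPLS.

    SIMPLS (de Jong 1993) extracts each weight as the dominant singular
    vector of the deflated cross-covariance X'y — for a single response that
    is the normalized covariance vector itself — and deflates the covariance
    through an orthonormal basis of the X-loadings.  For one response its
    predictions coincide with NIPALS PLS-1, which is exactly what makes it
    an independent oracle.  Returns the centered-data regression vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X0 = X - X.mean(axis=0)
    y0 = y - y.mean()
    p = X0.shape[1]
    s = X0.T @ y0
    R = np.zeros((p, k))
    Q = np.zeros(k)
    V = np.zeros((p, k))
    for j in range(k):
        r = s / np.linalg.norm(s)
        t = X0 @ r
        t_norm = np.linalg.norm(t)
        t = t / t_norm
        r = r / t_norm
        pj = X0.T @ t
        qj = float(y0 @ t)
        v = pj.copy()
        if j > 0:
            v -= V[:, :j] @ (V[:, :j].T @ pj)
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        R[:, j], Q[j], V[:, j] = r, qj, v
    return R @ Q


def ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares regression vector on centered data."""
    X0 = X - X.mean(axis=0)
    y0 = y - y.mean()
    return np.linalg.pinv(X0) @ y0


def linreg(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple linear regression y = a + b*x."""
    xm, ym = x.mean(), y.mean()
    b = float(((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm)))
    return ym - b * xm, b
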