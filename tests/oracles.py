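"""Independent dense-algebra oracles used to cross-check the package.

Everything here works with explicitly materialised and inverted matrices
(numpy.linalg on small n) and never calls the package's spectral code paths,
so agreement between the two routes is a genuine two-sided check.
"""

from __future__ import annotations

import numpy as np


def dense_restricted_loglik(y, X, G, h2):
    """Profiled restricted log-likelihood at fixed h² via dense inverses.

    V* = h²G + (1−h²)I; σ² is profiled out analytically. Uses the
    Patterson–Thompson form −½[(n−p)(log 2πσ̂² + 1) + log|V*| + log|XᵀV*⁻¹X|].
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    Vs = h2 * G + (1.0 - h2) * np.eye(n)
    Vi = np.linalg.inv(Vs)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / (n - p)
    return -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
        + np.linalg.slogdet(Vs)[1]
        + np.linalg.slogdet(A)[1]
    )


def dense_gls_wald(y, X, x, V0):
    """Wald statistic on the x coefficient from a joint GLS fit of y on
    [X, x] with known covariance V0. Returns (beta, se, wald)."""
    y = np.asarray(y, float).ravel()
    Vi = np.linalg.inv(V0)
    W = np.column_stack([X, x])
    A = np.linalg.inv(W.T @ Vi @ W)
    bhat = A @ W.T @ Vi @ y
    se = float(np.sqrt(A[-1, -1]))
    return float(bhat[-1]), se, float(bhat[-1] / se)


def dense_v0_solve(V0, v):
    return np.linalg.solve(V0, v)


def ols_slope_z(y, x, sigma_e2):
    """Large-sample slope statistic of the OLS regression of centered y on
    centered x with the residual variance fixed at sigma_e2."""
    yc = y - y.mean()
    xc = x - x.mean()
    beta = float(xc @ yc) / float(xc @ xc)
    se = float(np.sqrt(sigma_e2 / (xc @ xc)))
    return beta / se
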