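"""Step 1 of the two-step scan: REML fit of the null animal model.

The null model is  y = Xβ + u + e,  u ~ N(0, G·σu²),  e ~ N(0, I·σe²),
with one phenotype record per animal (the incidence matrix of the random
animal effect is the identity). Writing the total variance σ² = σu² + σe²
and the heritability h² = σu²/σ², the phenotypic covariance is

    V(h², σ²) = σ² · (h²·G + (1 − h²)·I).

On the eigenbasis of G = U·diag(d)·Uᵀ this is diagonal with entries
σ²·(h²·dᵢ + 1 − h²), so the restricted likelihood can be profiled over σ²
and maximised over the single parameter h² by a grid scan followed by
bounded 1-D refinement — globally robust and O(n) per evaluation after one
eigendecomposition.

The resulting :class:`NullFit` carries everything step 2 needs: the variance
components, GLS fixed-effect solutions, residuals, and the spectral
representation of V₀ = G·σ̂u² + I·σ̂e² for fast V₀⁻¹·v products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .grm import GRM

_H2_GRID_STEP = 0.01
_H2_MAX = 0.99
_H2_TOL = 1e-6
_MAX_REFINE_ITER = 200


@dataclass
class VarianceComponents:
    """REML variance-component estimates for the null animal model."""

    sigma_u2: float  # additive genetic variance (trait units²)
    sigma_e2: float  # residual variance (trait units²)
    loglik: float  # restricted log-likelihood at the optimum
    converged: bool  # False on boundary hit or iteration cap
    n_iter: int

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 <= 0:
            raise ValueError(
                f"invalid variance components: sigma_u2={self.sigma_u2}, "
                f"sigma_e2={self.sigma_e2}"
            )

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


class _Spectral:
    """Cached eigendecomposition of G with profiled-REML machinery."""

    def __init__(self, y: np.ndarray, X: np.ndarray, grm: GRM):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
        if grm.n != y.size:
            raise ValueError(f"G is {grm.n}×{grm.n} but y has {y.size} records")
        if not np.isfinite(y).all():
            raise ValueError("phenotype vector contains non-finite values")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]} columns)"
            )
        self.y, self.X, self.grm = y, X, grm
        self.n, self.p = X.shape
        d, U = np.linalg.eigh(grm.g)
        if d.min() <= 0:
            raise np.linalg.LinAlgError(
                f"G is not positive definite after ridge (min eigenvalue {d.min():.3e}); "
                "increase the GRM ridge"
            )
        self.d, self.U = d, U
        self.y_t = U.T @ y
        self.X_t = U.T @ X

    def _gls(self, h2: float):
        """GLS at V* = h²G + (1−h²)I; returns (beta, quad form, logdets)."""
        delta = h2 * self.d + (1.0 - h2)
        Xw = self.X_t / delta[:, None]
        A = self.X_t.T @ Xw  # Xᵀ V*⁻¹ X
        b = Xw.T @ self.y_t
        beta = np.linalg.solve(A, b)
        r_t = self.y_t - self.X_t @ beta
        quad = float(r_t @ (r_t / delta))
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("XᵀV⁻¹X not positive definite")
        return beta, quad, float(np.log(delta).sum()), logdet_A

    def profile_loglik(self, h2: float) -> float:
        """Restricted log-likelihood at fixed h², with σ² profiled out."""
        if not 0.0 <= h2 < 1.0:
            raise ValueError(f"h2 must lie in [0, 1), got {h2}")
        _, quad, logdet_V, logdet_A = self._gls(h2)
        nm = self.n - self.p
        sigma2 = quad / nm
        return -0.5 * (nm * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_V + logdet_A)


@dataclass
class NullFit:
    """Step-1 product: variance components plus the spectral form of V₀."""

    vc: VarianceComponents
    beta_hat: np.ndarray
    X: np.ndarray
    eigenvalues: np.ndarray  # of G (ridge included)
    eigenvectors: np.ndarray
    residuals: np.ndarray  # y − X·β̂
    y: np.ndarray
    ids: list[str]

    @property
    def v0_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of V₀ = G·σu² + I·σe² (same eigenvectors as G)."""
        return self.eigenvalues * self.vc.sigma_u2 + self.vc.sigma_e2

    def v0_dense(self) -> np.ndarray:
        """Materialise V₀ (for diagnostics / small-n cross-checks)."""
        return (self.eigenvectors * self.v0_eigenvalues) @ self.eigenvectors.T

    def v0_solve(self, v: np.ndarray) -> np.ndarray:
        """V₀⁻¹·v via the eigenbasis; accepts a vector or a column stack."""
        v = np.asarray(v, dtype=float)
        vt = self.eigenvectors.T @ v
        if v.ndim == 1:
            return self.eigenvectors @ (vt / self.v0_eigenvalues)
        return self.eigenvectors @ (vt / self.v0_eigenvalues[:, None])


def profile_loglik(y: np.ndarray, X: np.ndarray, grm: GRM, h2: float) -> float:
    """Restricted log-likelihood of the null model at fixed h², total
    variance profiled out. Convenience wrapper; for repeated evaluation use
    :func:`fit_null`, which shares one eigendecomposition."""
    return _Spectral(y, X, grm).profile_loglik(h2)


def fit_null(y: np.ndarray, X: np.ndarray | None, grm: GRM) -> NullFit:
    """Fit the null animal model by profiled REML.

    ``X`` defaults to an intercept-only design (the phenotype is a deviation
    already adjusted for systematic effects upstream). Returns a
    :class:`NullFit`; ``vc.converged`` is False when the optimum sits on the
    h² boundary (0 or the 0.99 cap) or the refinement hit its iteration cap.
    """
    y = np.asarray(y, dtype=float).ravel()
    if X is None:
        X = np.ones((y.size, 1))
    spec = _Spectral(y, X, grm)

    grid = np.arange(0.0, _H2_MAX + 1e-12, _H2_GRID_STEP)
    vals = [spec.profile_loglik(h) for h in grid]
    i0 = int(np.argmax(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = min(grid[min(i0 + 1, len(grid) - 1)], _H2_MAX)

    n_iter = len(grid)
    if hi > lo:
        res = minimize_scalar(
            lambda h: -spec.profile_loglik(h),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _H2_TOL, "maxiter": _MAX_REFINE_ITER},
        )
        h2_hat = float(res.x)
        n_iter += int(res.nfev)
        refined_ok = bool(res.success)
    else:
        h2_hat, refined_ok = float(lo), True

    beta, quad, _, _ = spec._gls(h2_hat)
    sigma2 = quad / (spec.n - spec.p)
    sigma_u2 = h2_hat * sigma2
    sigma_e2 = (1.0 - h2_hat) * sigma2
    boundary = h2_hat <= _H2_TOL or h2_hat >= _H2_MAX - _H2_TOL
    vc = VarianceComponents(
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        loglik=spec.profile_loglik(h2_hat),
        converged=refined_ok and not boundary,
        n_iter=n_iter,
    )
    return NullFit(
        vc=vc,
        beta_hat=beta,
        X=spec.X,
        eigenvalues=spec.d,
        eigenvectors=spec.U,
        residuals=y - spec.X @ beta,
        y=y,
        ids=list(grm.ids),
    )


def v0_solve(nf: NullFit, v: np.ndarray) -> np.ndarray:
    """Solve V₀·x = v against the step-1 covariance. Function-style alias of
    :meth:`NullFit.v0_solve`."""
    return nf.v0_solve(v)
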