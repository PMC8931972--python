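"""Penalized cubic B-spline smoother (P-spline) with GCV smoothing selection.

A small linear smoother used in two places: the residual-asymmetry diagnostic
of the phenology fit (generous basis, smoothing parameter chosen by
generalized cross-validation) and the spline candidate of the
altitude-abundance model comparison (basis dimension 4, fixed smoothing
parameter). The basis is a cubic B-spline with equally spaced interior knots
and a second-order difference penalty on the coefficients.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["PenalizedCubicSpline"]


def _bspline_knots(x: np.ndarray, basis_dim: int, degree: int = 3) -> np.ndarray:
    """Equally spaced knots extended past the data range (Eilers-Marx).

    Uniform spacing keeps polynomials up to the penalty order in the
    difference-penalty null space, so straight lines are never shrunk.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    n_seg = basis_dim - degree
    if n_seg < 1:
        raise ValueError(f"basis_dim must be >= {degree + 1}")
    d = (hi - lo) / n_seg if hi > lo else 1.0
    return lo + d * np.arange(-degree, n_seg + degree + 1)


class PenalizedCubicSpline(BaseEstimator, RegressorMixin):
    """Cubic P-spline regression of a single covariate.

    Parameters
    ----------
    basis_dim : int
        Number of B-spline basis functions (columns of the design matrix).
    lam : float or None
        Smoothing parameter. ``None`` selects it by minimising the GCV score
        ``n * RSS / (n - edf)**2`` over a geometric grid.
    penalty_order : int
        Order of the difference penalty on adjacent coefficients.

    Attributes
    ----------
    lam_ : float            selected / fixed smoothing parameter
    edf_ : float            effective degrees of freedom, trace of the hat matrix
    coef_ : ndarray         B-spline coefficients
    rss_ : float            residual sum of squares
    fitted_values_ : ndarray
    """

    def __init__(self, basis_dim: int = 10, lam: float | None = None, penalty_order: int = 2):
        self.basis_dim = basis_dim
        self.lam = lam
        self.penalty_order = penalty_order

    # -- internals ---------------------------------------------------------
    def _design(self, x: np.ndarray) -> np.ndarray:
        # extrapolate=True extends the boundary polynomial pieces, so the
        # fitted curve can be evaluated slightly outside the data range
        return BSpline.design_matrix(x, self.knots_, 3, extrapolate=True).toarray()

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        n = x.size
        if np.unique(x).size < self.basis_dim:
            raise ValueError(
                f"need at least basis_dim={self.basis_dim} distinct covariate values, "
                f"got {np.unique(x).size}"
            )
        self.knots_ = _bspline_knots(x, self.basis_dim)
        B = self._design(x)
        k = B.shape[1]
        D = np.diff(np.eye(k), n=self.penalty_order, axis=0)
        P = D.T @ D

        # Demmler-Reinsch: diagonalise the penalty in the B'B metric so every
        # lambda on the grid is O(nk) instead of a fresh linear solve.
        C = B.T @ B + 1e-10 * np.trace(B.T @ B) / k * np.eye(k)
        R = np.linalg.cholesky(C)
        Rinv = np.linalg.inv(R.T)  # R^{-T}, upper-triangular inverse
        s, U = np.linalg.eigh(Rinv.T @ P @ Rinv)
        s = np.clip(s, 0.0, None)
        s[s < 1e-10 * max(s.max(), 1.0)] = 0.0  # exact penalty null space
        Z = B @ (Rinv @ U)  # columns orthonormal in the implied metric
        c = Z.T @ y
        yty = float(y @ y)

        def profile(lam: float) -> tuple[float, float]:
            w = 1.0 / (1.0 + lam * s)
            edf = float(np.sum(w))
            resid = y - Z @ (c * w)  # direct form avoids cancellation at tiny RSS
            return float(resid @ resid), edf

        if self.lam is None:
            grid = np.geomspace(1e-8, 1e10, 181)
            scores = np.empty(grid.size)
            for i, lam in enumerate(grid):
                rss, edf = profile(lam)
                denom = max(n - edf, 1e-8)
                scores[i] = n * rss / denom**2
            # near-ties resolve toward the smoother fit (larger lambda); the
            # absolute floor covers exact-fit data where RSS is float noise
            tol = scores.min() * (1.0 + 1e-10) + 1e-10 * yty / n + 1e-300
            self.lam_ = float(grid[np.nonzero(scores <= tol)[0][-1]])
        else:
            self.lam_ = float(self.lam)

        w = 1.0 / (1.0 + self.lam_ * s)
        g = c * w
        self.coef_ = Rinv @ (U @ g)
        self.edf_ = float(np.sum(w))
        self.fitted_values_ = B @ self.coef_
        self.rss_ = float(np.sum((y - self.fitted_values_) ** 2))
        self.n_obs_ = n
        self._smoother_core = (Rinv @ U) * w  # k x k; hat row = B(x0) @ core @ Z.T
        self._Z = Z
        self._y = y
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self._design(x) @ self.coef_

    def prediction_se(self, X, scale: float | None = None) -> np.ndarray:
        """Pointwise SE of the fitted curve; ``scale`` defaults to RSS/(n-edf)."""
        check_is_fitted(self, "coef_")
        if scale is None:
            scale = self.rss_ / max(self.n_obs_ - self.edf_, 1.0)
        x = np.asarray(X, dtype=float).reshape(-1)
        L = self._design(x) @ self._smoother_core @ self._Z.T  # rows l(x0)
        return np.sqrt(scale * np.sum(L**2, axis=1))

    def smooth_test(self) -> tuple[float, float]:
        """Approximate test of the smooth against a constant mean.

        Pseudo-F statistic ``((RSS0 - RSS) / (edf - 1)) / (RSS / (n - edf))``
        with an F(edf-1, n-edf) reference; returns ``(edf, p_value)``.
        An edf near 1 (flat fit) yields p = 1.
        """
        check_is_fitted(self, "coef_")
        y = self._y
        rss0 = float(np.sum((y - y.mean()) ** 2))
        df1 = self.edf_ - 1.0
        df2 = self.n_obs_ - self.edf_
        if df1 < 1e-6 or df2 <= 0 or self.rss_ <= 0:
            return self.edf_, 1.0
        f = ((rss0 - self.rss_) / df1) / (self.rss_ / df2)
        p = float(stats.f.sf(f, df1, df2))
        return self.edf_, p
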