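"""Altitude-abundance models and the predicted elevation limit.

The seasonal maximum weekly egg count of each ovitrap (MEggs) is related to
trap altitude by four candidate regressions — linear, segmented (continuous
two-piece linear), exponential decay ``altitude = A * exp(-r * MEggs)`` and a
penalized-spline smooth — ranked by AICc. Altitude is the response and MEggs
the predictor, so the elevation limit (EL) where oviposition is predicted to
vanish is simply each model's fitted altitude at MEggs = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .phenology import aicc
from .simulate import band_label
from .smoothing import PenalizedCubicSpline

__all__ = [
    "compute_trap_maxima",
    "LinearElevationModel",
    "ExponentialDecayModel",
    "SegmentedElevationModel",
    "SplineElevationModel",
    "fit_elevation_model",
    "rank_models",
    "decay_confidence_band",
    "predict_band_abundance",
]


def compute_trap_maxima(survey: pd.DataFrame) -> pd.DataFrame:
    """Per-trap seasonal maximum weekly egg count (MEggs); all-zero traps kept."""
    if survey.empty:
        raise ValueError("survey table is empty")
    return (
        survey.groupby("trap_id", sort=True)
        .agg(altitude_m=("altitude_m", "first"), meggs=("eggs", "max"))
        .reset_index()
    )


def _as_xy(X, y=None) -> tuple[np.ndarray, np.ndarray]:
    if y is None and isinstance(X, pd.DataFrame):
        return X["meggs"].to_numpy(dtype=float), X["altitude_m"].to_numpy(dtype=float)
    x = np.asarray(X, dtype=float).reshape(-1)
    return x, np.asarray(y, dtype=float).reshape(-1)


def _gaussian_llf(rss: float, n: int) -> float:
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


class _ElevationBase(BaseEstimator, RegressorMixin):
    """Shared scoring for altitude ~ f(MEggs) regressions.

    Subclasses set ``fitted_values_`` and ``k_mean_`` during fit and then call
    ``_finalize``; AICc uses the Gaussian-error likelihood with
    k = mean parameters + 1 (the error variance).
    """

    kind: str = ""

    def _finalize(self, x: np.ndarray, y: np.ndarray) -> None:
        n = y.size
        resid = y - self.fitted_values_
        self.rss_ = float(resid @ resid)
        self.n_obs_ = int(n)
        self.k_params_ = float(self.k_mean_) + 1.0
        self.llf_ = _gaussian_llf(self.rss_, n)
        self.aicc_ = aicc(self.llf_, self.k_params_, n)
        tss = float(np.sum((y - y.mean()) ** 2))
        dfree = n - self.k_mean_
        self.adj_r2_ = 1.0 - (self.rss_ / dfree) / (tss / (n - 1)) if dfree > 0 and tss > 0 else np.nan
        self.data_fingerprint_ = hash((x.tobytes(), y.tobytes()))
        self.delta_aicc_ = None

    def elevation_limit(self) -> tuple[float, float]:
        """(EL, SE): fitted altitude at MEggs = 0."""
        check_is_fitted(self, "aicc_")
        return self.intercept_estimate_, self.intercept_se_


class LinearElevationModel(_ElevationBase):
    """Ordinary least squares: altitude = intercept + slope * MEggs."""

    kind = "linear"

    def fit(self, X, y=None):
        x, yv = _as_xy(X, y)
        res = sm.OLS(yv, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.fitted_values_ = np.asarray(res.fittedvalues)
        self.k_mean_ = 2
        self.intercept_estimate_ = self.intercept_
        self.intercept_se_ = float(res.bse[0])
        self.intercept_p_ = float(res.pvalues[0])
        self._finalize(x, yv)
        return self

    def predict(self, X):
        check_is_fitted(self, "aicc_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


class ExponentialDecayModel(_ElevationBase):
    """Least-squares fit of ``altitude = A * exp(-r * MEggs)``.

    A is initialised at the maximum observed altitude and r from a log-linear
    prefit on positive altitudes; the fit proceeds by damped Gauss-Newton,
    exploiting that A is linear given r (profiled closed form).
    """

    kind = "expdecay"

    def __init__(self, max_iter: int = 200, tol: float = 1e-12):
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _profile_A(x: np.ndarray, y: np.ndarray, r: float) -> float:
        u = np.exp(-r * x)
        return float((y @ u) / (u @ u))

    def fit(self, X, y=None):
        x, yv = _as_xy(X, y)
        if x.size < 6:
            raise ValueError("need at least 6 points")
        pos = yv > 0
        if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
            slope = np.polyfit(x[pos], np.log(yv[pos]), 1)[0]
            r = max(-slope, 1e-8)
        else:
            r = 1e-3
        A = float(np.max(yv))

        def rss_of(A_, r_):
            e = yv - A_ * np.exp(-r_ * x)
            return float(e @ e)

        rss = rss_of(A, r)
        for _ in range(self.max_iter):
            u = np.exp(-r * x)
            e = yv - A * u
            J = np.column_stack([u, -A * x * u])  # d(fitted)/d(A, r)
            g, *_ = np.linalg.lstsq(J, e, rcond=None)
            step = 1.0
            improved = False
            for _ in range(40):  # damping by step halving
                A_new, r_new = A + step * g[0], r + step * g[1]
                if r_new > 0:
                    rss_new = rss_of(A_new, r_new)
                    if rss_new <= rss:
                        improved = True
                        break
                step /= 2.0
            if not improved:
                break
            rel = (rss - rss_new) / max(rss, 1e-300)
            A, r, rss = A_new, r_new, rss_new
            A = self._profile_A(x, yv, r)  # exact in A at the current r
            rss = rss_of(A, r)
            if rel < self.tol or rss <= 1e-20 * float(yv @ yv):
                break
        else:
            raise RuntimeError(
                f"exponential decay fit did not converge in {self.max_iter} iterations "
                f"(last rss={rss:.6g}, A={A:.6g}, r={r:.6g})"
            )
        if A <= 0:
            raise RuntimeError(f"fitted decay intercept A={A:.6g} is not positive")

        self.A_, self.r_ = float(A), float(r)
        self.fitted_values_ = A * np.exp(-r * x)
        self.k_mean_ = 2
        # Gauss-Newton covariance: sigma^2 (J'J)^-1 evaluated at the optimum
        u = np.exp(-r * x)
        J = np.column_stack([u, -A * x * u])
        dof = max(x.size - 2, 1)
        s2 = rss / dof
        try:
            covp = s2 * np.linalg.inv(J.T @ J)
            self.param_cov_ = covp
            se_A = float(np.sqrt(covp[0, 0]))
        except np.linalg.LinAlgError:
            self.param_cov_ = None
            se_A = float("nan")
        self.intercept_estimate_ = self.A_
        self.intercept_se_ = se_A
        self.intercept_p_ = float(2 * stats.t.sf(abs(A / se_A), dof)) if se_A > 0 else 0.0
        self._finalize(x, yv)
        self.adj_r2_ = np.nan  # not defined for the nonlinear fit
        return self

    def predict(self, X):
        check_is_fitted(self, "aicc_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.A_ * np.exp(-self.r_ * x)


def _fast_decay_fit(x: np.ndarray, y: np.ndarray, r_grid: np.ndarray) -> tuple[float, float]:
    """Profiled grid + parabolic refinement; used inside the bootstrap."""
    U = np.exp(-np.outer(r_grid, x))  # ngrid x n
    S_yu = U @ y
    S_uu = np.einsum("ij,ij->i", U, U)
    rss = y @ y - S_yu**2 / S_uu
    i = int(np.argmin(rss))
    lo = r_grid[max(i - 1, 0)]
    hi = r_grid[min(i + 1, r_grid.size - 1)]
    from scipy.optimize import minimize_scalar

    def f(r):
        u = np.exp(-r * x)
        a = (y @ u) / (u @ u)
        e = y - a * u
        return e @ e

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    r = float(res.x)
    u = np.exp(-r * x)
    A = float((y @ u) / (u @ u))
    return A, r


class SegmentedElevationModel(_ElevationBase):
    """Continuous two-piece linear regression with an estimated breakpoint.

    altitude = b0 + b1*MEggs + b2*(MEggs - psi)+ ; the breakpoint psi is
    found by profiling least squares over a grid of candidate breakpoints,
    refined by iterative linearization (the working-hinge update
    psi <- psi + gamma/b2), with bootstrap restarts to escape local optima.
    At least ``min_side`` points are required on each side of the breakpoint.
    """

    kind = "segmented"

    def __init__(self, n_restarts: int = 10, min_side: int = 4, max_iter: int = 50,
                 random_state: int | None = 0):
        self.n_restarts = n_restarts
        self.min_side = min_side
        self.max_iter = max_iter
        self.random_state = random_state

    @staticmethod
    def _ols_at(x, y, psi):
        Xd = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        return beta, float(resid @ resid)

    def _refine(self, x, y, psi, lo, hi):
        """Muggeo-style linearization from a starting breakpoint."""
        best = (np.inf, psi, None)
        for _ in range(self.max_iter):
            U = np.clip(x - psi, 0.0, None)
            V = -(x > psi).astype(float)
            Xd = np.column_stack([np.ones_like(x), x, U, V])
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            if abs(beta[2]) < 1e-12:
                break
            step = beta[3] / beta[2]
            psi_new = float(np.clip(psi + step, lo, hi))
            _, rss = self._ols_at(x, y, psi_new)
            if rss < best[0]:
                best = (rss, psi_new, None)
            if abs(psi_new - psi) < 1e-10:
                psi = psi_new
                break
            psi = psi_new
        return best[1] if np.isfinite(best[0]) else psi

    def fit(self, X, y=None):
        x, yv = _as_xy(X, y)
        n = x.size
        if n < 2 * self.min_side:
            raise ValueError(f"need at least {2 * self.min_side} points")
        xs = np.sort(np.unique(x))
        lo, hi = np.sort(x)[self.min_side - 1], np.sort(x)[n - self.min_side]
        cand = xs[(xs > lo) & (xs < hi)]
        if cand.size == 0:
            cand = np.array([float(np.median(x))])
        # profile over observed-x candidates, then linearize from the best
        rss_cand = [self._ols_at(x, yv, p)[1] for p in cand]
        psi = float(cand[int(np.argmin(rss_cand))])
        psi = self._refine(x, yv, psi, lo, hi)
        beta, rss = self._ols_at(x, yv, psi)

        rng = np.random.default_rng(self.random_state)
        for _ in range(self.n_restarts):  # bootstrap restarting
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], yv[idx]
            try:
                cb = np.sort(np.unique(xb))
                cb = cb[(cb > lo) & (cb < hi)]
                if cb.size == 0:
                    continue
                rb = [self._ols_at(xb, yb, p)[1] for p in cb]
                psi_b = self._refine(xb, yb, float(cb[int(np.argmin(rb))]), lo, hi)
            except np.linalg.LinAlgError:
                continue
            psi_try = self._refine(x, yv, psi_b, lo, hi)
            beta_try, rss_try = self._ols_at(x, yv, psi_try)
            if rss_try < rss - 1e-12:
                psi, beta, rss = psi_try, beta_try, rss_try

        self.psi_ = float(psi)
        self.intercept_ = float(beta[0])
        self.slopes_ = (float(beta[1]), float(beta[1] + beta[2]))
        Xd = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        res = sm.OLS(yv, Xd).fit()
        # breakpoint SE via the gamma/beta2 ratio of the working model
        U = np.clip(x - psi, 0.0, None)
        V = -(x > psi).astype(float)
        resw = sm.OLS(yv, np.column_stack([np.ones_like(x), x, U, V])).fit()
        b2 = resw.params[2]
        self.psi_se_ = float(abs(resw.bse[3] / b2)) if abs(b2) > 1e-12 else float("nan")
        self.fitted_values_ = np.asarray(res.fittedvalues)
        self.k_mean_ = 4  # intercept, two slopes, breakpoint
        self.intercept_estimate_ = self.intercept_
        self.intercept_se_ = float(res.bse[0])
        self.intercept_p_ = float(res.pvalues[0])
        self._finalize(x, yv)
        return self

    def predict(self, X):
        check_is_fitted(self, "aicc_")
        x = np.asarray(X, dtype=float).reshape(-1)
        b1, b2 = self.slopes_[0], self.slopes_[1] - self.slopes_[0]
        return self.intercept_ + b1 * x + b2 * np.clip(x - self.psi_, 0.0, None)


class SplineElevationModel(_ElevationBase):
    """Penalized-spline smooth of altitude on MEggs (cubic basis, fixed
    smoothing parameter); the additive-model candidate of the comparison."""

    kind = "gam"

    def __init__(self, basis_dim: int = 4, sp: float = 0.1):
        self.basis_dim = basis_dim
        self.sp = sp

    def fit(self, X, y=None):
        x, yv = _as_xy(X, y)
        self.spline_ = PenalizedCubicSpline(basis_dim=self.basis_dim, lam=self.sp)
        self.spline_.fit(x, yv)
        self.edf_ = self.spline_.edf_
        self.fitted_values_ = self.spline_.fitted_values_
        self.k_mean_ = self.edf_
        x0 = np.array([0.0])
        self.intercept_estimate_ = float(self.spline_.predict(x0)[0])
        self.intercept_se_ = float(self.spline_.prediction_se(x0)[0])
        dof = max(x.size - self.edf_, 1.0)
        self.intercept_p_ = float(
            2 * stats.t.sf(abs(self.intercept_estimate_ / self.intercept_se_), dof)
        )
        self._finalize(x, yv)
        return self

    def predict(self, X):
        check_is_fitted(self, "aicc_")
        return self.spline_.predict(X)


_KINDS = {
    "linear": LinearElevationModel,
    "expdecay": ExponentialDecayModel,
    "segmented": SegmentedElevationModel,
    "gam": SplineElevationModel,
}


def fit_elevation_model(data: pd.DataFrame, kind: str, **options):
    """Fit one candidate altitude ~ MEggs model ('linear', 'segmented',
    'expdecay' or 'gam') to a trap-maxima table."""
    if kind not in _KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](**options).fit(data)


def rank_models(fits: list) -> list:
    """Order fitted candidates by ascending AICc and attach delta_aicc_.

    All fits must come from the same data; ties break toward fewer
    parameters.
    """
    if not fits:
        raise ValueError("no fits to rank")
    prints = {f.data_fingerprint_ for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were not computed on identical data")
    ranked = sorted(fits, key=lambda f: (f.aicc_, f.k_params_))
    best = ranked[0].aicc_
    for f in ranked:
        f.delta_aicc_ = f.aicc_ - best
    return ranked


def _bca_interval(theta_hat: float, boot: np.ndarray, jack: np.ndarray,
                  level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for one statistic."""
    boot = np.asarray(boot, dtype=float)
    alpha = (1.0 - level) / 2.0
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (boot.size + 1)), 1.0 - 1.0 / (boot.size + 1))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for alph in (alpha, 1.0 - alpha):
        z = stats.norm.ppf(alph)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def decay_confidence_band(
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed=None,
    grid: np.ndarray | None = None,
    level: float = 0.95,
    max_failed_frac: float = 0.10,
) -> dict:
    """Case-resampling BCa band for the exponential-decay curve and its EL.

    Bootstraps (A, r) by resampling traps, evaluates the fitted curve on a
    MEggs grid, and returns pointwise BCa intervals plus the BCa interval of
    the intercept (the elevation limit). More than ``max_failed_frac`` failed
    refits aborts.
    """
    x, y = _as_xy(data)
    fit = ExponentialDecayModel().fit(x, y)
    if grid is None:
        grid = np.linspace(0.0, float(x.max()), 101)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    r_grid = np.geomspace(max(fit.r_ / 20.0, 1e-8), fit.r_ * 20.0, 80)

    boot_A = np.empty(n_boot)
    boot_r = np.empty(n_boot)
    failed = 0
    kept = 0
    n = x.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            A_b, r_b = _fast_decay_fit(x[idx], y[idx], r_grid)
            if not (np.isfinite(A_b) and np.isfinite(r_b) and A_b > 0):
                raise FloatingPointError
        except Exception:
            failed += 1
            continue
        boot_A[kept] = A_b
        boot_r[kept] = r_b
        kept += 1
    if failed > max_failed_frac * n_boot:
        raise RuntimeError(f"{failed}/{n_boot} bootstrap refits failed")
    boot_A, boot_r = boot_A[:kept], boot_r[:kept]

    jack_A = np.empty(n)
    jack_r = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack_A[i], jack_r[i] = _fast_decay_fit(x[mask], y[mask], r_grid)
        mask[i] = True

    curve_hat = fit.A_ * np.exp(-fit.r_ * grid)
    boot_curves = boot_A[:, None] * np.exp(-np.outer(boot_r, grid))
    jack_curves = jack_A[:, None] * np.exp(-np.outer(jack_r, grid))
    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    for j in range(grid.size):
        lo[j], hi[j] = _bca_interval(curve_hat[j], boot_curves[:, j], jack_curves[:, j], level)
    intercept_ci = _bca_interval(fit.A_, boot_A, jack_A, level)
    return {
        "fit": fit,
        "grid": grid,
        "curve": curve_hat,
        "lower": lo,
        "upper": hi,
        "intercept_ci": intercept_ci,
        "n_failed": failed,
    }


def predict_band_abundance(fit: ExponentialDecayModel, bands) -> pd.DataFrame:
    """Predicted MEggs bounds per altitude band under the decay law.

    Inverts ``altitude = A * exp(-r * MEggs)``: meggs(alt) = ln(A/alt)/r for
    0 < alt <= A, else 0. Within each band the minimum sits at the high edge
    and the maximum at the low edge; bands entirely above the elevation limit
    A get (0, 0), and the band containing A has its upper edge replaced by A.
    A band starting at sea level is clamped to the prediction at 1 m and
    flagged (the law diverges at altitude 0).
    """
    check_is_fitted(fit, "aicc_")
    A, r = fit.A_, fit.r_

    def meggs_at(alt: float) -> float:
        if alt <= 0 or alt >= A:
            return 0.0
        return float(np.log(A / alt) / r)

    rows = []
    for low, high in bands:
        if low < 0:
            raise ValueError("band altitudes must be >= 0")
        clamped = False
        hi_eff = min(high, A)
        if low >= A:
            mmin = mmax = 0.0
        else:
            mmin = meggs_at(hi_eff)
            if low == 0.0:
                mmax = meggs_at(1.0)
                clamped = True
            else:
                mmax = meggs_at(low)
        rows.append(
            {
                "band": band_label(low, high),
                "low_m": float(low),
                "high_m": float(hi_eff),
                "meggs_min": mmin,
                "meggs_max": mmax,
                "clamped": clamped,
            }
        )
    return pd.DataFrame(rows)
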