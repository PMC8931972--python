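"""Gaussian phenology of weekly ovitrap egg counts.

A log-quadratic count GLM — log E[mEggs_w] = b0 + b1*DOY + b2*DOY^2 per
altitudinal band — is a Gaussian curve in time. Its coefficients map in
closed form to the phenological metrics

    mu    = -b1 / (2 b2)          peak day of year
    sigma = sqrt(-1 / (2 b2))     spread of the season (days)
    h     = exp(b0 - b1^2/(4 b2)) peak weekly mean egg count
    N     = h * sigma * sqrt(2*pi)  seasonal egg-abundance index

with delta-method standard errors and parametric-bootstrap confidence
intervals propagated from the coefficient covariance. Derived activity
windows (80% egg-laying interval, observable activity period, first/last
day of egg laying) follow from (mu, sigma, h) alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .simulate import band_label, doy_of_week
from .smoothing import PenalizedCubicSpline

__all__ = [
    "GaussianPhenologyGLM",
    "PhenologyMetrics",
    "AsymmetryResult",
    "aggregate_weekly_means",
    "fit_gaussian_phenology",
    "aicc",
    "derive_metrics",
    "metric_gradients",
    "metric_standard_errors",
    "metric_confidence_intervals",
    "phenology_windows",
    "asymmetry_test",
]

#: z quantile of the 90th percentile; the 10th-90th interpercentile range of a
#: Gaussian season spans 2 * Z90 * sigma days ("80EA").
Z90 = 1.2815516


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Second-order (small-sample) Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n_obs <= k_params + 1:
        raise ValueError(f"AICc undefined for n_obs={n_obs} <= k_params+1={k_params + 1}")
    k = k_params
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n_obs - k - 1.0)


# ---------------------------------------------------------------------------
# weekly aggregation
# ---------------------------------------------------------------------------

def aggregate_weekly_means(
    survey: pd.DataFrame,
    band_edges: list[float] | None = None,
    weeks: tuple[int, int] = (23, 49),
) -> pd.DataFrame:
    """Per-band, per-week mean egg count (mEggs_w), zeros included.

    ``survey`` needs columns trap_id, week, eggs and either a ``band`` column
    or ``altitude_m`` plus ``band_edges`` (ascending altitudes) to assign one.
    Weeks outside ``weeks`` are dropped. A band interval containing no trap
    raises, naming the band.
    """
    if survey.empty:
        raise ValueError("survey table is empty")
    df = survey.copy()
    if band_edges is not None:
        edges = np.asarray(band_edges, dtype=float)
        labels = [band_label(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
        idx = np.searchsorted(edges, df["altitude_m"].to_numpy(), side="right") - 1
        idx = np.clip(idx, 0, None)
        if (idx >= len(labels)).any() or (df["altitude_m"].to_numpy() < edges[0]).any():
            bad = df.loc[(idx >= len(labels)) | (df["altitude_m"] < edges[0]), "trap_id"].unique()
            raise ValueError(f"traps outside the band edges: {list(bad)}")
        df["band"] = [labels[i] for i in idx]
        present = set(df["band"])
        missing = [lab for lab in labels if lab not in present]
        if missing:
            raise ValueError(f"no traps in band(s): {missing}")
    elif "band" not in df.columns:
        raise ValueError("survey has no 'band' column and no band_edges were given")

    df = df[(df["week"] >= weeks[0]) & (df["week"] <= weeks[1])]
    out = (
        df.groupby(["band", "week"], sort=True)["eggs"]
        .mean()
        .rename("meggs_w")
        .reset_index()
    )
    out["doy"] = doy_of_week(out["week"])
    return out[["band", "week", "doy", "meggs_w"]]


# ---------------------------------------------------------------------------
# metric closed forms, gradients, windows
# ---------------------------------------------------------------------------

def derive_metrics(b0: float, b1: float, b2: float) -> tuple[float, float, float, float]:
    """(mu, sigma, N, h) from the log-quadratic coefficients; needs b2 < 0."""
    if not b2 < 0:
        raise ValueError("no interior peak: quadratic coefficient must be negative")
    mu = -b1 / (2.0 * b2)
    sigma = np.sqrt(-1.0 / (2.0 * b2))
    h = np.exp(b0 - b1**2 / (4.0 * b2))
    N = h * sigma * np.sqrt(2.0 * np.pi)
    return float(mu), float(sigma), float(N), float(h)


def metric_gradients(b0: float, b1: float, b2: float) -> dict[str, np.ndarray]:
    """Analytic gradients of (mu, sigma, N, h) in (b0, b1, b2).

    Compact forms: grad h = h*(1, mu, mu^2); grad N = N*(1, mu, mu^2+sigma^2);
    grad mu = sigma^2*(0, 1, 2 mu); grad sigma = (0, 0, sigma^3).
    """
    mu, sigma, N, h = derive_metrics(b0, b1, b2)
    return {
        "mu": np.array([0.0, sigma**2, 2.0 * mu * sigma**2]),
        "sigma": np.array([0.0, 0.0, sigma**3]),
        "N": N * np.array([1.0, mu, mu**2 + sigma**2]),
        "h": h * np.array([1.0, mu, mu**2]),
    }


def metric_standard_errors(b: np.ndarray, cov: np.ndarray) -> dict[str, float]:
    """Delta-method SEs of (mu, sigma, N, h): sqrt(g' V g) per metric."""
    cov = np.asarray(cov, dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise ValueError("coefficient covariance is not positive semi-definite")
    grads = metric_gradients(*b)
    return {k: float(np.sqrt(max(g @ cov @ g, 0.0))) for k, g in grads.items()}


def metric_confidence_intervals(
    b: np.ndarray,
    cov: np.ndarray,
    n_sim: int = 10_000,
    random_state=None,
    level: float = 0.95,
) -> dict:
    """Parametric-bootstrap percentile CIs of (mu, sigma, N, h).

    Coefficient vectors are simulated from MVN(b, cov); draws without an
    interior peak (b2 >= 0) are discarded and counted. More than 50%
    discarded draws aborts (the fitted shape is unstable).
    """
    rng = np.random.default_rng(random_state)
    draws = rng.multivariate_normal(np.asarray(b, float), np.asarray(cov, float), size=n_sim,
                                    method="svd")
    ok = draws[:, 2] < 0
    n_bad = int(n_sim - ok.sum())
    if n_bad > n_sim / 2:
        raise ValueError(f"{n_bad}/{n_sim} simulated coefficient draws have no interior peak")
    d = draws[ok]
    mu = -d[:, 1] / (2.0 * d[:, 2])
    sigma = np.sqrt(-1.0 / (2.0 * d[:, 2]))
    h = np.exp(d[:, 0] - d[:, 1] ** 2 / (4.0 * d[:, 2]))
    N = h * sigma * np.sqrt(2.0 * np.pi)
    q = [100 * (1 - level) / 2, 100 * (1 + level) / 2]
    out = {"n_discarded": n_bad}
    for name, vals in [("mu", mu), ("sigma", sigma), ("N", N), ("h", h)]:
        lo, hi = np.percentile(vals, q)
        out[name] = (float(lo), float(hi))
    return out


def phenology_windows(
    mu: float, sigma: float, h: float, zero_threshold: float = 0.5
) -> tuple[float, float, float, float]:
    """Activity windows (ea80, oap, first_doy, last_doy) from (mu, sigma, h).

    ea80: days between the 10th and 90th percentile of the season,
    ``2 * 1.2815516 * sigma`` rounded to whole days. oap: days on which the
    fitted curve predicts more than one egg, ``2 * sigma * sqrt(2 ln h)``
    (0 when h <= 1). first/last day: integer days bounding the interval where
    the predicted weekly mean reaches ``zero_threshold`` (the day the curve
    first rounds up to a whole egg, by default); NaN when the peak itself
    stays below the threshold.
    """
    if sigma <= 0 or h < 0:
        raise ValueError("need sigma > 0 and h >= 0")
    ea80 = float(np.round(2.0 * Z90 * sigma))
    oap = float(np.round(2.0 * sigma * np.sqrt(2.0 * np.log(h)))) if h > 1.0 else 0.0
    if h > zero_threshold:
        half = sigma * np.sqrt(2.0 * np.log(h / zero_threshold))
        first_doy = float(np.round(mu - half))
        last_doy = float(np.round(mu + half))
    else:
        first_doy = last_doy = float("nan")
    return ea80, oap, first_doy, last_doy


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PhenologyMetrics:
    band: str
    mu: float
    sigma: float
    N: float
    h: float
    se_mu: float
    se_sigma: float
    se_N: float
    se_h: float
    ci_mu: tuple[float, float]
    ci_sigma: tuple[float, float]
    ci_N: tuple[float, float]
    ci_h: tuple[float, float]
    ea80: float
    oap: float
    first_doy: float
    last_doy: float


@dataclass
class AsymmetryResult:
    """Effective df and approximate p-value of the residual smooth; edf
    meaningfully above 1 indicates an asymmetric seasonal pattern."""

    edf: float
    p_value: float
    basis_dim: int


# ---------------------------------------------------------------------------
# negative binomial helpers (glm.nb-style alternation)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _ml_theta(y: np.ndarray, mu: np.ndarray) -> float:
    res = minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, float(np.exp(lt))),
        bounds=(-7.0, 14.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class GaussianPhenologyGLM(BaseEstimator):
    """Log-quadratic count GLM of weekly mean egg counts per altitudinal band.

    Fits ``log E[y] = b0_band + b1_band*DOY + b2_band*DOY^2`` — band enters as
    a categorical factor fully interacted with DOY and DOY^2, so every band
    gets its own Gaussian curve while a negative-binomial fit shares one
    dispersion. The NB dispersion theta is estimated by maximum likelihood,
    alternating IRLS for the mean with a profile-likelihood update of theta.

    Parameters
    ----------
    family : {"negbin", "poisson", "auto"}
        Count family; "auto" fits both and keeps the lower AICc.
    integerize : bool
        Round the weekly means to integers before fitting (count families
        expect integral responses). Switchable for sensitivity checks.
    min_nonzero_weeks : int
        Bands with fewer distinct non-zero weeks cannot support a Gaussian
        fit and raise.

    Attributes (after fit)
    ----------------------
    bands_ : list of band labels
    coef_ : DataFrame of (b0, b1, b2) per band
    cov_ : full coefficient covariance; ``band_cov(band)`` gives 3x3 blocks
    theta_ : NB dispersion (None for Poisson)
    family_, llf_, aicc_, n_obs_, k_params_, null_deviance_, deviance_
    b2_nonneg_ : bands flagged for a non-concave (no-peak) fit
    """

    def __init__(
        self,
        family: str = "negbin",
        integerize: bool = True,
        min_nonzero_weeks: int = 4,
        max_iter: int = 50,
        tol: float = 1e-8,
    ):
        self.family = family
        self.integerize = integerize
        self.min_nonzero_weeks = min_nonzero_weeks
        self.max_iter = max_iter
        self.tol = tol

    # -- design ------------------------------------------------------------
    @staticmethod
    def _design(bands: list[str], band: np.ndarray, doy: np.ndarray) -> np.ndarray:
        n = doy.size
        X = np.zeros((n, 3 * len(bands)))
        for j, lab in enumerate(bands):
            m = band == lab
            X[m, 3 * j] = 1.0
            X[m, 3 * j + 1] = doy[m]
            X[m, 3 * j + 2] = doy[m] ** 2
        return X

    def fit(self, X: pd.DataFrame, y=None):
        """Fit from a weekly series table (columns band, doy, meggs_w), or
        from ``X`` with columns (band, doy) and a separate response ``y``."""
        df = X.copy()
        if y is not None:
            df = df.assign(meggs_w=np.asarray(y, dtype=float))
        if not {"band", "doy", "meggs_w"}.issubset(df.columns):
            raise ValueError("need columns band, doy and meggs_w (or a y argument)")
        if (df["meggs_w"] < 0).any():
            raise ValueError("weekly means must be non-negative")

        bands = sorted(df["band"].unique())
        short = [
            lab
            for lab in bands
            if (df.loc[(df["band"] == lab) & (df["meggs_w"] > 0), "doy"].nunique()
                < self.min_nonzero_weeks)
        ]
        if short:
            raise ValueError(
                f"insufficient non-zero weeks to fit a Gaussian model in band(s): {short}"
            )

        yv = df["meggs_w"].to_numpy(dtype=float)
        if self.integerize:
            yv = np.round(yv)
        doy = df["doy"].to_numpy(dtype=float)
        bandv = df["band"].to_numpy()
        Xd = self._design(bands, bandv, doy)

        if self.family == "auto":
            fits = []
            for fam in ("poisson", "negbin"):
                est = GaussianPhenologyGLM(
                    family=fam,
                    integerize=False,  # already rounded above
                    min_nonzero_weeks=self.min_nonzero_weeks,
                    max_iter=self.max_iter,
                    tol=self.tol,
                )
                est.fit(df.assign(meggs_w=yv))
                fits.append(est)
            best = min(fits, key=lambda e: e.aicc_)
            self.__dict__.update(best.__dict__)
            self.family = "auto"
            self.candidate_aicc_ = {e.family_: e.aicc_ for e in fits}
            return self

        if self.family == "poisson":
            res = sm.GLM(yv, Xd, family=sm.families.Poisson()).fit()
            theta = None
            llf = float(res.llf)
            k = Xd.shape[1]
        elif self.family == "negbin":
            theta = 1.0
            res = None
            for _ in range(self.max_iter):
                res = sm.GLM(
                    yv, Xd, family=sm.families.NegativeBinomial(alpha=1.0 / theta)
                ).fit()
                theta_new = _ml_theta(yv, res.fittedvalues)
                if abs(np.log(theta_new / theta)) < self.tol:
                    theta = theta_new
                    break
                theta = theta_new
            res = sm.GLM(
                yv, Xd, family=sm.families.NegativeBinomial(alpha=1.0 / theta)
            ).fit()
            llf = float(res.llf)
            k = Xd.shape[1] + 1  # dispersion counts as a parameter
        else:
            raise ValueError(f"unknown family {self.family!r}")

        if not res.converged:
            raise RuntimeError(
                f"GLM failed to converge after {res.fit_history['iteration']} IRLS iterations"
            )

        self.bands_ = bands
        self.family_ = self.family
        self.theta_ = theta
        self.coef_ = pd.DataFrame(
            res.params.reshape(len(bands), 3), index=bands, columns=["b0", "b1", "b2"]
        )
        self.cov_ = np.asarray(res.cov_params())
        self.llf_ = llf
        self.n_obs_ = int(yv.size)
        self.k_params_ = int(k)
        self.aicc_ = aicc(llf, k, yv.size)
        self.deviance_ = float(res.deviance)
        self.null_deviance_ = float(res.null_deviance)
        self.df_resid_ = int(res.df_resid)
        self.resid_deviance_ = np.asarray(res.resid_deviance)
        self._fit_doy = doy
        self._fit_band = bandv
        self._fit_y = yv
        self.b2_nonneg_ = [lab for lab in bands if self.coef_.loc[lab, "b2"] >= 0]
        if self.b2_nonneg_:
            warnings.warn(
                f"non-concave fit (b2 >= 0) in band(s) {self.b2_nonneg_}; "
                "phenological metrics are undefined there",
                stacklevel=2,
            )
        return self

    # -- prediction and per-band accessors ----------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted mean weekly egg count for rows with (band, doy)."""
        Xd = self._design(
            self.bands_, X["band"].to_numpy(), X["doy"].to_numpy(dtype=float)
        )
        flat = self.coef_.to_numpy().reshape(-1)
        return np.exp(Xd @ flat)

    def band_coef(self, band: str) -> np.ndarray:
        return self.coef_.loc[band].to_numpy()

    def band_cov(self, band: str) -> np.ndarray:
        j = self.bands_.index(band)
        sl = slice(3 * j, 3 * j + 3)
        return self.cov_[sl, sl]

    # -- metrics -------------------------------------------------------------
    def metrics(self, band: str) -> tuple[float, float, float, float]:
        return derive_metrics(*self.band_coef(band))

    def standard_errors(self, band: str) -> dict[str, float]:
        return metric_standard_errors(self.band_coef(band), self.band_cov(band))

    def confidence_intervals(
        self, band: str, n_sim: int = 10_000, random_state=None
    ) -> dict:
        return metric_confidence_intervals(
            self.band_coef(band), self.band_cov(band), n_sim=n_sim, random_state=random_state
        )

    def windows(self, band: str, zero_threshold: float = 0.5):
        mu, sigma, _, h = self.metrics(band)
        return phenology_windows(mu, sigma, h, zero_threshold=zero_threshold)

    def summary_metrics(
        self,
        n_sim: int = 10_000,
        random_state=None,
        zero_threshold: float = 0.5,
    ) -> pd.DataFrame:
        """One row per band with metrics, SEs, CIs and activity windows."""
        rows = []
        rng = np.random.default_rng(random_state)
        for band in self.bands_:
            if band in self.b2_nonneg_:
                continue
            mu, sigma, N, h = self.metrics(band)
            se = self.standard_errors(band)
            ci = self.confidence_intervals(band, n_sim=n_sim, random_state=rng)
            ea80, oap, first_doy, last_doy = phenology_windows(
                mu, sigma, h, zero_threshold=zero_threshold
            )
            rows.append(
                PhenologyMetrics(
                    band=band, mu=mu, sigma=sigma, N=N, h=h,
                    se_mu=se["mu"], se_sigma=se["sigma"], se_N=se["N"], se_h=se["h"],
                    ci_mu=ci["mu"], ci_sigma=ci["sigma"], ci_N=ci["N"], ci_h=ci["h"],
                    ea80=ea80, oap=oap, first_doy=first_doy, last_doy=last_doy,
                ).__dict__
            )
        return pd.DataFrame(rows)

    def asymmetry_test(self, basis_dim: int = 12) -> AsymmetryResult:
        """Penalized cubic spline of the deviance residuals on DOY.

        The Gaussian curve is symmetric about its peak; systematic residual
        structure over DOY (edf of the GCV-chosen smooth above 1, small
        p-value) signals an asymmetric season. The reported edf excludes the
        constant — edf = 1 means the residual smooth collapses to a straight
        line, the usual convention for a single smooth term.
        """
        spline = PenalizedCubicSpline(basis_dim=basis_dim, lam=None)
        spline.fit(self._fit_doy, self.resid_deviance_)
        edf_trace, p = spline.smooth_test()
        return AsymmetryResult(edf=max(edf_trace - 1.0, 1.0), p_value=p, basis_dim=basis_dim)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_gaussian_phenology(
    series: pd.DataFrame, family: str = "negbin", **kwargs
) -> GaussianPhenologyGLM:
    """Fit the per-band Gaussian count GLM to a weekly series table."""
    return GaussianPhenologyGLM(family=family, **kwargs).fit(series)


def asymmetry_test(
    fit: GaussianPhenologyGLM, series: pd.DataFrame | None = None, basis_dim: int = 12
) -> AsymmetryResult:
    """Residual-asymmetry diagnostic of a fitted phenology model."""
    return fit.asymmetry_test(basis_dim=basis_dim)
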