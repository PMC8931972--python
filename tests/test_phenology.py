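"""Gaussian phenology: aggregation, GLM fitting, metric algebra, uncertainty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

import altiphen as ap
from altiphen.phenology import Z90

from conftest import BAND_MU, BAND_SIGMA


def _mini_survey(rows):
    df = pd.DataFrame(rows, columns=["trap_id", "band", "week", "eggs"])
    df["altitude_m"] = 100.0
    df["locality"] = "L"
    df["doy"] = 7 * df["week"] - 3
    return df


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_weekly_mean_is_arithmetic_mean_including_zeros():
    survey = _mini_survey(
        [("a", "B", 30, 10), ("b", "B", 30, 20), ("c", "B", 30, 30),
         ("a", "B", 31, 0), ("b", "B", 31, 10)]
    )
    out = ap.aggregate_weekly_means(survey)
    assert out.loc[out["week"] == 30, "meggs_w"].item() == 20.0
    assert out.loc[out["week"] == 31, "meggs_w"].item() == 5.0
    assert (out["doy"] == 7 * out["week"] - 3).all()


def test_weeks_outside_interval_dropped_and_empty_band_raises():
    survey = _mini_survey([("a", "B", 10, 5), ("a", "B", 30, 5)])
    out = ap.aggregate_weekly_means(survey)
    assert set(out["week"]) == {30}
    with pytest.raises(ValueError, match="0-50m"):
        ap.aggregate_weekly_means(
            survey.assign(altitude_m=100.0).drop(columns="band"),
            band_edges=[0, 50, 200],
        )


def test_aggregated_series_matches_generating_curve(survey, weekly_series):
    """Generator round-trip: the aggregated band means follow the generating
    Gaussian within Monte-Carlo error."""
    cfg = ap.SimulationConfig(seed=1)
    traps = survey.groupby("band")["trap_id"].nunique()
    for j, band in enumerate(sorted(weekly_series["band"].unique())):
        sub = weekly_series[weekly_series["band"] == band]
        alts = survey.loc[survey["band"] == band, ["trap_id", "altitude_m"]].drop_duplicates()
        h_traps = np.log(cfg.decay_A / alts["altitude_m"]) / cfg.decay_r
        h_band = h_traps.mean()
        curve = h_band * np.exp(-((sub["doy"] - cfg.mu_doy[j]) ** 2) / (2 * cfg.sigma_days[j] ** 2))
        n = traps[band]
        mc_se = np.sqrt((curve + curve**2 / cfg.theta) / n)
        assert (np.abs(sub["meggs_w"] - curve) < 4 * mc_se + 2.0).mean() > 0.9


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------

def test_aicc_arithmetic_and_large_n_limit():
    assert ap.aicc(-10.0, 2, 100) == pytest.approx(24.0 + 12.0 / 97.0, abs=1e-12)
    aic = -2 * (-10.0) + 2 * 2
    assert abs(ap.aicc(-10.0, 2, 10**9) - aic) < 1e-6
    with pytest.raises(ValueError):
        ap.aicc(-10.0, 5, 6)


# ---------------------------------------------------------------------------
# metric closed forms vs numeric oracles
# ---------------------------------------------------------------------------

def test_derive_metrics_closed_form_against_numeric_oracle():
    b0, b1, b2 = np.log(100.0), 0.0, -5e-4
    mu, sigma, N, h = ap.derive_metrics(b0, b1, b2)
    assert mu == pytest.approx(0.0, abs=1e-12)
    assert sigma == pytest.approx(np.sqrt(1000.0), rel=1e-9)  # 31.6228
    assert h == pytest.approx(100.0, rel=1e-12)
    assert N == pytest.approx(7926.65, abs=0.01)
    # oracle: numeric peak finding and quadrature of exp(b0 + b1 t + b2 t^2)
    f = lambda t: np.exp(b0 + b1 * t + b2 * t**2)
    res = minimize_scalar(lambda t: -f(t), bounds=(-500, 500), method="bounded")
    assert abs(res.x - mu) < 1e-5
    assert f(res.x) == pytest.approx(h, rel=1e-9)
    area, _ = quad(f, -np.inf, np.inf)
    assert area == pytest.approx(N, rel=1e-9)


@given(
    mu=st.floats(150, 300),
    sigma=st.floats(10, 60),
    logh=st.floats(0.5, 6.5),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_metric_identities_hold_for_any_gaussian(mu, sigma, logh):
    """N = h*sigma*sqrt(2pi) and ea80 = 2*z90*sigma, h-independent."""
    b2 = -1.0 / (2 * sigma**2)
    b1 = -2 * b2 * mu
    b0 = logh - b1 * mu - b2 * mu**2  # so that exp(b0 + b1 mu + b2 mu^2) = h
    m, s, N, h = ap.derive_metrics(b0, b1, b2)
    assert m == pytest.approx(mu, rel=1e-9, abs=1e-6)
    assert s == pytest.approx(sigma, rel=1e-9)
    assert N == pytest.approx(h * s * np.sqrt(2 * np.pi), rel=1e-9)
    ea80 = ap.phenology_windows(m, s, max(h, 1.01))[0]
    assert ea80 == np.round(2 * Z90 * s)


def test_no_interior_peak_raises():
    with pytest.raises(ValueError, match="peak"):
        ap.derive_metrics(1.0, 0.1, 0.0)


def test_translation_equivariance_of_refit():
    """Shifting the DOY origin shifts mu and leaves sigma, h, N unchanged."""
    doy = np.arange(158, 341, 7.0)
    mu, sigma, h = 234.0, 30.0, 200.0
    y = np.round(h * np.exp(-((doy - mu) ** 2) / (2 * sigma**2)))
    base = pd.DataFrame({"band": "B", "doy": doy, "meggs_w": y})
    shifted = base.assign(doy=doy + 50)
    f1 = ap.GaussianPhenologyGLM(family="poisson").fit(base)
    f2 = ap.GaussianPhenologyGLM(family="poisson").fit(shifted)
    m1, m2 = f1.metrics("B"), f2.metrics("B")
    assert m2[0] - m1[0] == pytest.approx(50.0, abs=1e-6)
    np.testing.assert_allclose(m1[1:], m2[1:], rtol=1e-6)


def test_count_scaling_property():
    """Scaling counts by c multiplies h and N by c; mu, sigma, ea80 unchanged."""
    doy = np.arange(158, 341, 7.0)
    y = np.round(100 * np.exp(-((doy - 230.0) ** 2) / (2 * 30.0**2)))
    base = pd.DataFrame({"band": "B", "doy": doy, "meggs_w": y})
    f1 = ap.GaussianPhenologyGLM(family="poisson").fit(base)
    f4 = ap.GaussianPhenologyGLM(family="poisson").fit(base.assign(meggs_w=4 * y))
    m1, m4 = f1.metrics("B"), f4.metrics("B")
    assert m4[0] == pytest.approx(m1[0], rel=1e-9)        # mu
    assert m4[1] == pytest.approx(m1[1], rel=1e-9)        # sigma
    assert m4[3] == pytest.approx(4 * m1[3], rel=1e-9)    # h
    assert m4[2] == pytest.approx(4 * m1[2], rel=1e-9)    # N
    assert f4.band_coef("B")[0] - f1.band_coef("B")[0] == pytest.approx(np.log(4), rel=1e-9)


# ---------------------------------------------------------------------------
# fitting behaviour
# ---------------------------------------------------------------------------

def test_noiseless_fit_recovers_generating_triple():
    mu, sigma, h = 234.0, 33.13, 285.0
    doy = np.arange(158, 341, 7.0)
    y = np.round(h * np.exp(-((doy - mu) ** 2) / (2 * sigma**2)))
    series = pd.DataFrame({"band": "0-200m", "doy": doy, "meggs_w": y})
    fit = ap.GaussianPhenologyGLM(family="poisson").fit(series)
    mu_h, sg_h, _, h_h = fit.metrics("0-200m")
    assert mu_h == pytest.approx(mu, rel=0.01)
    assert sg_h == pytest.approx(sigma, rel=0.01)
    assert h_h == pytest.approx(h, rel=0.01)


def test_constant_counts_flagged_as_non_gaussian():
    doy = np.arange(158, 341, 7.0)
    series = pd.DataFrame({"band": "B", "doy": doy, "meggs_w": 7.0})
    with pytest.warns(UserWarning, match="non-concave"):
        fit = ap.GaussianPhenologyGLM(family="poisson").fit(series)
    assert "B" in fit.b2_nonneg_
    with pytest.raises(ValueError):
        fit.metrics("B")


def test_insufficient_nonzero_weeks_raises():
    doy = np.arange(158, 341, 7.0)
    y = np.zeros_like(doy)
    y[:3] = 5.0
    series = pd.DataFrame({"band": "B", "doy": doy, "meggs_w": y})
    with pytest.raises(ValueError, match="insufficient non-zero"):
        ap.GaussianPhenologyGLM().fit(series)


def test_nb_at_huge_theta_matches_poisson(weekly_series):
    """Family-limit equivalence: an NB fit constrained to theta -> inf agrees
    with the Poisson fit (oracle) on the same data."""
    import statsmodels.api as sm
    from altiphen.phenology import GaussianPhenologyGLM

    pois = GaussianPhenologyGLM(family="poisson").fit(weekly_series)
    df = weekly_series
    y = np.round(df["meggs_w"].to_numpy())
    X = GaussianPhenologyGLM._design(pois.bands_, df["band"].to_numpy(), df["doy"].to_numpy(float))
    nb = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1e-10)).fit()
    np.testing.assert_allclose(nb.params, pois.coef_.to_numpy().reshape(-1), rtol=1e-6)


def test_auto_family_prefers_lower_aicc(weekly_series):
    auto = ap.GaussianPhenologyGLM(family="auto").fit(weekly_series)
    assert set(auto.candidate_aicc_) == {"poisson", "negbin"}
    assert auto.aicc_ == min(auto.candidate_aicc_.values())
    assert auto.candidate_aicc_["negbin"] < auto.candidate_aicc_["poisson"]


# ---------------------------------------------------------------------------
# uncertainty: delta method, bootstrap CIs
# ---------------------------------------------------------------------------

def test_delta_gradients_match_finite_differences():
    rng = np.random.default_rng(123)
    for _ in range(100):
        mu = rng.uniform(150, 300)
        sigma = rng.uniform(10, 60)
        b2 = -1 / (2 * sigma**2)
        b1 = -2 * b2 * mu
        b0 = rng.uniform(0, 6) - b1 * mu - b2 * mu**2
        grads = ap.metric_gradients(b0, b1, b2)
        b = np.array([b0, b1, b2])
        for k, idx in [("mu", 0), ("sigma", 1), ("N", 2), ("h", 3)]:
            for j in range(3):
                hstep = 1e-6 * max(abs(b[j]), 1e-3)
                bp, bm = b.copy(), b.copy()
                bp[j] += hstep
                bm[j] -= hstep
                fd = (ap.derive_metrics(*bp)[idx] - ap.derive_metrics(*bm)[idx]) / (2 * hstep)
                ref = grads[k][j]
                assert fd == pytest.approx(ref, rel=2e-5, abs=1e-8)


def test_zero_covariance_gives_zero_se_and_point_cis():
    b = np.array([5.0, 0.23, -5e-4])
    V = np.zeros((3, 3))
    ses = ap.metric_standard_errors(b, V)
    assert all(v == 0.0 for v in ses.values())
    ci = ap.metric_confidence_intervals(b, V, n_sim=500, random_state=0)
    mets = ap.derive_metrics(*b)
    for name, val in zip(["mu", "sigma", "N", "h"], mets):
        lo, hi = ci[name]
        assert lo == pytest.approx(val, rel=1e-9)
        assert hi == pytest.approx(val, rel=1e-9)


def test_non_psd_covariance_rejected():
    b = np.array([5.0, 0.23, -5e-4])
    V = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(ValueError, match="positive semi-definite"):
        ap.metric_standard_errors(b, V)


def test_bootstrap_ci_matches_delta_in_normal_limit(nb_fit):
    """With a well-conditioned fit the percentile CI of mu is close to the
    delta-method normal interval."""
    band = nb_fit.bands_[0]
    mu = nb_fit.metrics(band)[0]
    se = nb_fit.standard_errors(band)["mu"]
    ci = nb_fit.confidence_intervals(band, n_sim=20_000, random_state=0)["mu"]
    lo, hi = mu - 1.96 * se, mu + 1.96 * se
    assert ci[0] == pytest.approx(lo, abs=0.1 * se + 0.15)
    assert ci[1] == pytest.approx(hi, abs=0.1 * se + 0.15)
    assert ci[0] < mu < ci[1]


def test_bootstrap_ci_seed_stability(nb_fit):
    band = nb_fit.bands_[0]
    sigma = nb_fit.metrics(band)[1]
    a = nb_fit.confidence_intervals(band, n_sim=10_000, random_state=1)
    b = nb_fit.confidence_intervals(band, n_sim=10_000, random_state=2)
    for k in ("mu", "sigma", "N", "h"):
        half_a = (a[k][1] - a[k][0]) / 2
        half_b = (b[k][1] - b[k][0]) / 2
        assert abs(half_a - half_b) < 0.02 * sigma * max(1.0, half_a / sigma)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sigma,expected", [(33.13, 85), (24.96, 64)])
def test_ea80_from_sigma(sigma, expected):
    assert ap.phenology_windows(230.0, sigma, 50.0)[0] == expected


def test_oap_threshold_and_published_value():
    assert ap.phenology_windows(230.0, 25.0, 1.0)[1] == 0.0
    h = 1156.30 / (29.71 * np.sqrt(2 * np.pi))  # 15.53
    assert ap.phenology_windows(228.0, 29.71, h)[1] == 139


def test_windows_monotone_in_h_and_sigma():
    base = ap.phenology_windows(230.0, 25.0, 10.0)[1]
    assert ap.phenology_windows(230.0, 25.0, 20.0)[1] > base
    assert ap.phenology_windows(230.0, 30.0, 10.0)[1] > base


def test_first_last_doy_undefined_below_threshold():
    ea80, oap, first, last = ap.phenology_windows(230.0, 25.0, 0.4)
    assert np.isnan(first) and np.isnan(last)
    assert oap == 0.0


# ---------------------------------------------------------------------------
# asymmetry diagnostic (distributional checks live in test_acceptance)
# ---------------------------------------------------------------------------

def test_asymmetry_detects_strong_skew():
    cfg = ap.SimulationConfig(seed=77, skew=4.0)
    series = ap.aggregate_weekly_means(ap.simulate_survey(cfg))
    fit = ap.GaussianPhenologyGLM(family="negbin").fit(series)
    res = fit.asymmetry_test()
    assert res.edf > 1.5
    assert res.p_value < 0.01
    assert res.basis_dim == 12


def test_asymmetry_requires_enough_distinct_doy(nb_fit):
    with pytest.raises(ValueError, match="distinct"):
        nb_fit.asymmetry_test(basis_dim=40)
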