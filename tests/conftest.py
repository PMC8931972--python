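"""Shared fixtures: study-design constants and small synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

import altiphen as ap

# Published per-band phenology metrics of the emulated study (inputs for
# worked examples and generator settings): peak day mu, Gaussian SD sigma,
# egg-abundance index N, and the printed activity windows.
BAND_MU = (234.0, 229.0, 232.0, 238.0, 228.0)
BAND_SIGMA = (33.13, 29.24, 24.96, 27.45, 29.71)
BAND_N = (23_643.80, 16_815.62, 10_268.70, 7_101.87, 1_156.30)
BAND_H_PRINTED = (285, 229, 164, 103, 16)
BAND_EA80 = (85, 75, 64, 70, 76)
BAND_OAP = (223, 193, 159, 167, 139)
BAND_FIRST_DOY = (117, 127, 148, 149, 150)
BAND_LAST_DOY = (352, 331, 316, 327, 305)

# Abundance-altitude decay law and segmented-fit parameters used by the
# recovery checks: altitude = A * exp(-r * MEggs).
DECAY_A = 1015.0
DECAY_R = 0.003
SEG_BREAKPOINT = 206.0
SEG_SLOPES = (-2.66, -0.76)
SEG_INTERCEPT = 1010.13


@pytest.fixture(scope="session")
def table_metrics():
    return {
        "mu": BAND_MU,
        "sigma": BAND_SIGMA,
        "N": BAND_N,
        "h": BAND_H_PRINTED,
        "ea80": BAND_EA80,
        "oap": BAND_OAP,
        "first_doy": BAND_FIRST_DOY,
        "last_doy": BAND_LAST_DOY,
    }


@pytest.fixture(scope="session")
def default_config():
    return ap.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def survey(default_config):
    return ap.simulate_survey(default_config)


@pytest.fixture(scope="session")
def weekly_series(survey):
    return ap.aggregate_weekly_means(survey)


@pytest.fixture(scope="session")
def nb_fit(weekly_series):
    return ap.GaussianPhenologyGLM(family="negbin").fit(weekly_series)


@pytest.fixture(scope="session")
def noiseless_decay_data():
    m = np.arange(0.0, 601.0, 50.0)
    return pd.DataFrame(
        {
            "trap_id": [f"T{i}" for i in range(m.size)],
            "altitude_m": DECAY_A * np.exp(-DECAY_R * m),
            "meggs": m,
        }
    )
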