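"""Synthetic ovitrap surveys with the statistical structure the analysis assumes.

The generator mirrors the study design it is meant to exercise: localities in
200-m altitudinal bands, at least three ovitraps per locality, weekly egg
counts over an active season, negative-binomial dispersion around a
log-quadratic (Gaussian-in-time) seasonal mean whose peak height decays
exponentially with altitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "simulate_survey",
    "simulate_trap_maxima",
    "band_label",
]

#: Default 200-m altitudinal bands, 0-1000 m asl.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 200.0),
    (200.0, 400.0),
    (400.0, 600.0),
    (600.0, 800.0),
    (800.0, 1000.0),
)

#: Per-band peak day of year and Gaussian SD (days) of the seasonal curve.
DEFAULT_MU_DOY: tuple[float, ...] = (234.0, 229.0, 232.0, 238.0, 228.0)
DEFAULT_SIGMA_DAYS: tuple[float, ...] = (33.13, 29.24, 24.96, 27.45, 29.71)


def band_label(low: float, high: float) -> str:
    """Human-readable label for an altitude interval, e.g. ``'0-200m'``."""
    return f"{low:g}-{high:g}m"


def doy_of_week(week) -> np.ndarray:
    """Mid-week day of year for an ISO-style week number (doy = 7*week - 3)."""
    return 7 * np.asarray(week) - 3


@dataclass
class SimulationConfig:
    """Parameters of the synthetic ovitrap survey.

    Parameters
    ----------
    bands
        Altitude intervals ``(low_m, high_m)`` in metres asl.
    localities_per_band, traps_per_locality
        Survey effort; the emulated design uses >= 3 traps per locality.
    weeks
        Inclusive week interval of the sampling season.
    mu_doy, sigma_days
        Per-band peak day of year and Gaussian SD (days) of the seasonal
        oviposition curve.
    decay_A, decay_r
        Intercept (m asl) and rate (1 / eggs) of the abundance-altitude law
        ``altitude = A * exp(-r * MEggs)``; inverted to set each trap's peak.
    peak_meggs
        Optional per-band peak weekly mean egg counts. When given they
        override the decay-law inversion (useful for phenology-only studies).
    peak_scale
        Multiplier applied to the decay-law-implied peak; 1.0 makes a trap's
        expected peak weekly count equal the law's MEggs at its altitude.
    theta
        Negative-binomial dispersion (variance ``m + m**2 / theta``);
        ``theta -> inf`` approaches Poisson counts.
    skew
        Asymmetry of the seasonal mean; 0 gives a symmetric Gaussian curve,
        positive values an exponentially-modulated (right-skewed) shape.
    seed
        Seed of the generator; identical configs yield identical tables.
    """

    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS
    localities_per_band: int = 2
    traps_per_locality: int = 3
    weeks: tuple[int, int] = (23, 49)
    mu_doy: Sequence[float] = DEFAULT_MU_DOY
    sigma_days: Sequence[float] = DEFAULT_SIGMA_DAYS
    decay_A: float = 1015.0
    decay_r: float = 0.003
    peak_meggs: Sequence[float] | None = None
    peak_scale: float = 1.0
    theta: float = 5.0
    skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.bands = tuple(tuple(float(v) for v in b) for b in self.bands)
        self.weeks = tuple(int(w) for w in self.weeks)
        self.mu_doy = tuple(float(v) for v in self.mu_doy)
        self.sigma_days = tuple(float(v) for v in self.sigma_days)
        if self.peak_meggs is not None:
            self.peak_meggs = tuple(float(v) for v in self.peak_meggs)
        self.validate()

    def validate(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("at least one altitude band is required")
        for low, high in self.bands:
            if not low < high:
                raise ValueError(f"band ({low}, {high}) must have low < high")
        if len(self.mu_doy) != len(self.bands) or len(self.sigma_days) != len(self.bands):
            raise ValueError("mu_doy and sigma_days must have one entry per band")
        if any(s <= 0 for s in self.sigma_days):
            raise ValueError("sigma_days must be positive")
        if self.peak_meggs is not None:
            if len(self.peak_meggs) != len(self.bands):
                raise ValueError("peak_meggs must have one entry per band")
            if any(h < 0 for h in self.peak_meggs):
                raise ValueError("peak_meggs must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.decay_A <= 0 or self.decay_r <= 0:
            raise ValueError("decay_A and decay_r must be positive")
        if self.weeks[1] < self.weeks[0]:
            raise ValueError("weeks interval is empty")
        if self.traps_per_locality < 1 or self.localities_per_band < 1:
            raise ValueError("need at least one trap per locality and one locality per band")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = [tuple(b) for b in d["bands"]]
        return cls(**d)


def _seasonal_shape(doy: np.ndarray, mu: float, sigma: float, skew: float) -> np.ndarray:
    """Unit-peak seasonal shape: Gaussian, or skew-normal-shaped when skew != 0."""
    if skew == 0.0:
        return np.exp(-((doy - mu) ** 2) / (2.0 * sigma**2))
    z = (doy - mu) / sigma
    dens = stats.norm.pdf(z) * stats.norm.cdf(skew * z)
    # normalise to unit peak on a fine grid so `h` keeps its meaning
    zg = np.linspace(-6.0, 6.0, 4001)
    peak = (stats.norm.pdf(zg) * stats.norm.cdf(skew * zg)).max()
    return dens / peak


def _implied_meggs(altitude: np.ndarray, A: float, r: float) -> np.ndarray:
    """Invert altitude = A*exp(-r*MEggs); altitudes above A clamp to 0."""
    alt = np.asarray(altitude, dtype=float)
    out = np.zeros_like(alt)
    ok = (alt > 0) & (alt < A)
    out[ok] = np.log(A / alt[ok]) / r
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite seasonal mean; check sigma_days and skew")
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _trap_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per trap: id, locality, band label and a uniform altitude."""
    rows = []
    for b, (low, high) in enumerate(config.bands):
        lab = band_label(low, high)
        for j in range(config.localities_per_band):
            loc = f"B{b + 1}L{j + 1}"
            for t in range(config.traps_per_locality):
                alt = rng.uniform(low, high)
                rows.append(
                    {
                        "trap_id": f"{loc}T{t + 1}",
                        "locality": loc,
                        "altitude_m": alt,
                        "band": lab,
                        "band_index": b,
                    }
                )
    return pd.DataFrame(rows)


def simulate_survey(config: SimulationConfig) -> pd.DataFrame:
    """Simulate weekly ovitrap egg counts.

    For every trap and week the count is drawn from a negative binomial with
    mean ``h_trap * shape(doy)`` where ``shape`` is the (possibly skewed)
    unit-peak seasonal curve of the trap's band and ``h_trap`` is the peak
    weekly egg count implied by the abundance-altitude decay law at the
    trap's altitude (or the per-band override ``peak_meggs``).

    Returns a table with columns
    ``trap_id, locality, altitude_m, band, week, doy, eggs``.
    """
    rng = np.random.default_rng(config.seed)
    traps = _trap_frame(config, rng)
    weeks = np.arange(config.weeks[0], config.weeks[1] + 1)
    doy = doy_of_week(weeks).astype(float)

    frames = []
    for _, trap in traps.iterrows():
        b = int(trap["band_index"])
        if config.peak_meggs is not None:
            h = float(config.peak_meggs[b])
        else:
            h = config.peak_scale * float(
                _implied_meggs(np.array([trap["altitude_m"]]), config.decay_A, config.decay_r)[0]
            )
        mean = h * _seasonal_shape(doy, config.mu_doy[b], config.sigma_days[b], config.skew)
        eggs = _nb_draw(rng, mean, config.theta)
        frames.append(
            pd.DataFrame(
                {
                    "trap_id": trap["trap_id"],
                    "locality": trap["locality"],
                    "altitude_m": trap["altitude_m"],
                    "band": trap["band"],
                    "week": weeks,
                    "doy": doy.astype(int),
                    "eggs": eggs.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trap_maxima(
    config: SimulationConfig,
    mode: str = "survey",
    noise_sd_m: float = 0.0,
    n_traps: int | None = None,
) -> pd.DataFrame:
    """Simulate per-trap seasonal maximum weekly egg counts (MEggs).

    mode="survey"
        Runs :func:`simulate_survey` and takes each trap's maximum weekly
        count; MEggs then inherits the counting noise of the survey.
    mode="inverse"
        Draws trap altitudes uniformly (per band, or over the full gradient
        when ``n_traps`` is given), sets MEggs by inverting the decay law at
        the noise-free altitude, and records ``altitude + N(0, noise_sd_m)``
        clipped at sea level, so that marginally
        ``altitude = A * exp(-r * MEggs) + noise``. Traps drawn above the
        decay intercept ``A`` get MEggs = 0 and are flagged ``clamped``.

    Returns columns ``trap_id, altitude_m, meggs`` (plus ``clamped`` in
    inverse mode).
    """
    if mode == "survey":
        survey = simulate_survey(config)
        out = (
            survey.groupby("trap_id", sort=True)
            .agg(altitude_m=("altitude_m", "first"), meggs=("eggs", "max"))
            .reset_index()
        )
        return out
    if mode != "inverse":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(config.seed)
    if n_traps is not None:
        low = min(b[0] for b in config.bands)
        high = max(b[1] for b in config.bands)
        alt_clean = rng.uniform(low, high, size=n_traps)
    else:
        parts = []
        per_band = config.localities_per_band * config.traps_per_locality
        for lo, hi in config.bands:
            parts.append(rng.uniform(lo, hi, size=per_band))
        alt_clean = np.concatenate(parts)
    meggs = _implied_meggs(alt_clean, config.decay_A, config.decay_r)
    clamped = alt_clean >= config.decay_A
    altitude = alt_clean
    if noise_sd_m > 0:
        altitude = np.clip(alt_clean + rng.normal(0.0, noise_sd_m, size=alt_clean.size), 0.0, None)
    return pd.DataFrame(
        {
            "trap_id": [f"T{i + 1:03d}" for i in range(alt_clean.size)],
            "altitude_m": altitude,
            "meggs": meggs,
            "clamped": clamped,
        }
    )
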