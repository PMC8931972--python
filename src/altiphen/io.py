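"""CSV/YAML/JSON I/O and the end-to-end pipeline.

All tables are plain comma-separated UTF-8 with a mandatory header and "."
decimals; dates travel as integer day-of-year. Every written artifact records
the seed and a hash of the run configuration so deterministic stages are
reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elevation import (
    compute_trap_maxima,
    decay_confidence_band,
    fit_elevation_model,
    predict_band_abundance,
    rank_models,
)
from .phenology import GaussianPhenologyGLM, aggregate_weekly_means
from .simulate import SimulationConfig
from .surveillance import classify_municipalities

log = logging.getLogger("altiphen")

SURVEY_COLUMNS = ["trap_id", "locality", "altitude_m", "band", "week", "doy", "eggs"]
TRAPMAX_COLUMNS = ["trap_id", "altitude_m", "meggs"]


def read_survey(path) -> pd.DataFrame:
    """Read and validate an ovitrap survey CSV.

    Requires the documented header, non-negative integer egg counts, and one
    record per (trap_id, week); duplicates are rejected naming the key.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"survey file {path} is missing or empty")
    df = pd.read_csv(path)
    missing = [c for c in ("trap_id", "week", "eggs") if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} lacks required column(s) {missing}")
    bad = df.index[df["eggs"].isna() | (df["eggs"] < 0) | (df["eggs"] % 1 != 0)]
    if len(bad):
        raise ValueError(
            f"malformed egg count at line {int(bad[0]) + 2} of {path} "
            "(counts must be non-negative integers)"
        )
    dup = df.duplicated(subset=["trap_id", "week"])
    if dup.any():
        key = df.loc[dup, ["trap_id", "week"]].iloc[0]
        raise ValueError(
            f"duplicate record for trap_id={key['trap_id']!r} week={int(key['week'])}"
        )
    df["eggs"] = df["eggs"].astype(int)
    log.info("read %d survey rows from %s", len(df), path)
    return df


def write_survey(df: pd.DataFrame, path) -> None:
    cols = [c for c in SURVEY_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_trap_maxima(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"trap-maxima file {path} is missing or empty")
    df = pd.read_csv(path)
    missing = [c for c in TRAPMAX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trap-maxima file {path} lacks column(s) {missing}")
    if (df["meggs"] < 0).any() or df["meggs"].isna().any():
        raise ValueError("meggs must be non-negative")
    return df


def write_trap_maxima(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_municipalities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"name", "mean_altitude_m", "area_km2", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"municipality file lacks column(s) {sorted(missing)}")
    return df


def load_sim_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def save_sim_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    survey_path: str | None = None
    municipalities_path: str | None = None
    out_dir: str = "altiphen_out"
    band_edges: list = field(default_factory=lambda: [0, 200, 400, 600, 800, 1000])
    weeks: tuple[int, int] = (23, 49)
    family: str = "auto"
    n_sim: int = 10_000
    n_boot: int = 1000
    seed: int = 0
    zero_threshold: float = 0.5
    verbosity: str = "INFO"

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Aggregate -> fit both families -> AICc select -> metrics/CIs/windows ->
    asymmetry test -> elevation model comparison -> EL -> band predictions ->
    municipality classification, writing CSV/JSON artifacts along the way.

    Stages whose inputs are unavailable are skipped with a logged reason;
    a stage failure raises a structured error naming the stage, with partial
    outputs left on disk.
    """
    logging.basicConfig(level=config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "package_version": __version__,
        "stages": {},
    }
    artifacts: dict = {"report": report}

    def _stage(name, fn):
        try:
            res = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_report(report, out)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        report["stages"][name] = {"status": "ok"}
        return res

    survey = _stage("read_survey", lambda: read_survey(config.survey_path))

    series = _stage(
        "aggregate",
        lambda: aggregate_weekly_means(
            survey,
            band_edges=None if "band" in survey.columns else config.band_edges,
            weeks=tuple(config.weeks),
        ),
    )

    def _fit():
        model = GaussianPhenologyGLM(family=config.family)
        model.fit(series)
        return model

    model = _stage("fit_phenology", _fit)
    report["phenology"] = {
        "family": model.family_,
        "theta": model.theta_,
        "aicc": model.aicc_,
        "candidates": getattr(model, "candidate_aicc_", None),
        "null_deviance": model.null_deviance_,
        "residual_deviance": model.deviance_,
        "coefficients": {b: list(model.band_coef(b)) for b in model.bands_},
    }

    metrics = _stage(
        "metrics",
        lambda: model.summary_metrics(
            n_sim=config.n_sim, random_state=config.seed,
            zero_threshold=config.zero_threshold,
        ),
    )
    metrics.to_csv(out / "phenology_metrics.csv", index=False)
    artifacts["metrics"] = metrics

    asym = _stage("asymmetry", model.asymmetry_test)
    report["asymmetry"] = {"edf": asym.edf, "p_value": asym.p_value, "basis_dim": asym.basis_dim}

    n_bands = survey["band"].nunique() if "band" in survey.columns else len(config.band_edges) - 1
    if n_bands < 2:
        log.info("elevation stage skipped: a single altitude band has no gradient")
        report["stages"]["elevation"] = {"status": "skipped",
                                         "reason": "single altitude band"}
    else:
        trapmax = _stage("trap_maxima", lambda: compute_trap_maxima(survey))
        write_trap_maxima(trapmax, out / "trap_maxima.csv")

        def _compare():
            fits = [fit_elevation_model(trapmax, k) for k in
                    ("linear", "segmented", "expdecay", "gam")]
            return rank_models(fits)

        ranked = _stage("elevation", _compare)
        comparison = pd.DataFrame(
            [
                {
                    "kind": f.kind,
                    "k_params": f.k_params_,
                    "aicc": f.aicc_,
                    "delta_aicc": f.delta_aicc_,
                    "intercept": f.intercept_estimate_,
                    "intercept_se": f.intercept_se_,
                    "adj_r2": f.adj_r2_,
                }
                for f in ranked
            ]
        )
        comparison.to_csv(out / "elevation_comparison.csv", index=False)
        artifacts["elevation_comparison"] = comparison
        best = ranked[0]
        report["elevation"] = {
            "best_kind": best.kind,
            "elevation_limit_m": best.intercept_estimate_,
            "elevation_limit_se": best.intercept_se_,
        }
        if best.kind == "expdecay":
            band_ci = _stage(
                "bootstrap_band",
                lambda: decay_confidence_band(trapmax, n_boot=config.n_boot, seed=config.seed),
            )
            report["elevation"]["el_ci_bca"] = list(band_ci["intercept_ci"])
            edges = list(config.band_edges)
            bands = list(zip(edges[:-1], edges[1:]))
            if best.A_ > edges[-1]:
                bands.append((edges[-1], best.A_))
            preds = predict_band_abundance(best, bands)
            preds.to_csv(out / "band_predictions.csv", index=False)
            artifacts["band_predictions"] = preds

            if config.municipalities_path:
                muni = _stage("municipalities",
                              lambda: read_municipalities(config.municipalities_path))
                classified, summary = _stage(
                    "classify",
                    lambda: classify_municipalities(muni, best.A_, config.band_edges),
                )
                classified.to_csv(out / "municipality_classes.csv", index=False)
                summary.to_csv(out / "municipality_summary.csv", index=False)
                artifacts["municipality_summary"] = summary

    _write_report(report, out)
    return artifacts


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
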