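"""Municipality classification against the predicted elevation limit.

Given mean municipality altitudes, the predicted elevation limit (EL) of
oviposition and the altitude bands of the abundance model, summarise how much
of a region — municipalities, area, population — falls inside the zone where
the vector is predicted to occur and therefore needs surveillance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import band_label

__all__ = ["classify_municipalities"]


def classify_municipalities(
    records: pd.DataFrame,
    el_m: float,
    band_edges,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each municipality to an altitude band and summarise coverage.

    ``records`` needs columns name, mean_altitude_m, area_km2, population.
    A municipality is below the elevation limit iff its mean altitude is
    at most ``el_m`` (the boundary counts as below: surveillance-inclusive).
    Rows with a missing altitude are flagged, excluded from the ratios and
    counted in the summary.

    Returns ``(classified, summary)``: the per-municipality table with
    ``band`` and ``below_el`` columns, and a per-band summary with counts,
    total area, and area / population percentages, plus below/above-EL and
    flagged rows.
    """
    if el_m <= 0:
        raise ValueError("elevation limit must be positive")
    edges = np.asarray(band_edges, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("band_edges must be ascending with at least two values")

    df = records.copy()
    required = {"name", "mean_altitude_m", "area_km2", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"municipality table needs columns {sorted(required)}")

    flagged = df["mean_altitude_m"].isna()
    ok = df.loc[~flagged].copy()
    labels = [band_label(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    top = edges[-1]

    alt = ok["mean_altitude_m"].to_numpy(dtype=float)
    # left-open bands (low, high]; altitude exactly on an edge joins the
    # band below it, consistent with the inclusive boundary rule at the EL
    idx = np.searchsorted(edges, alt, side="left") - 1
    idx = np.clip(idx, 0, None)
    band = np.asarray(
        [labels[min(i, len(labels) - 1)] if a <= top else f">{top:g}m" for i, a in zip(idx, alt)],
        dtype=object,
    )
    ok["band"] = band
    ok["below_el"] = alt <= el_m

    out = df.copy()
    out["band"] = pd.NA
    out["below_el"] = pd.NA
    out.loc[~flagged, "band"] = ok["band"].to_numpy()
    out.loc[~flagged, "below_el"] = ok["below_el"].to_numpy()

    tot_area = float(ok["area_km2"].sum())
    tot_pop = float(ok["population"].sum())

    def _row(label: str, sub: pd.DataFrame) -> dict:
        return {
            "group": label,
            "n": int(len(sub)),
            "area_km2": float(sub["area_km2"].sum()),
            "area_pct": 100.0 * float(sub["area_km2"].sum()) / tot_area if tot_area else np.nan,
            "population_pct": 100.0 * float(sub["population"].sum()) / tot_pop if tot_pop else np.nan,
        }

    rows = [_row(lab, ok[ok["band"] == lab]) for lab in labels]
    above_band = f">{top:g}m"
    if (ok["band"] == above_band).any():
        rows.append(_row(above_band, ok[ok["band"] == above_band]))
    rows.append(_row("below_el", ok[ok["below_el"]]))
    rows.append(_row("above_el", ok[~ok["below_el"]]))
    summary = pd.DataFrame(rows)
    summary.attrs["n_flagged"] = int(flagged.sum())
    return out, summary
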