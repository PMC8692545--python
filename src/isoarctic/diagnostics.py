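"""Derived quantities: N*, decadal means, linear trends, sector gradients."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boxmodel import Trajectory

__all__ = [
    "SelectionError",
    "nstar",
    "decadal_mean",
    "sector_gradient",
    "linear_trend",
    "summary_table",
]

DELTA_VARIABLES = ("d15n_no3", "d15n_pom")


class SelectionError(ValueError):
    """Empty box/year selection or a sector with no members."""


def nstar(no3, po4):
    """N* = NO3 − 16·PO4 (mmol m⁻³); a linear water-mass tracer."""
    return np.asarray(no3) - 16.0 * np.asarray(po4)


def _area_weights(traj: Trajectory, boxes: list[str]) -> np.ndarray:
    w = np.array([traj.area_of(b) for b in boxes], dtype=float)
    return w / w.sum()


def decadal_mean(
    traj: Trajectory,
    variable: str,
    year_range: tuple[int, int],
    boxes: list[str] | None = None,
) -> float:
    """Mean of a variable over a year range: unweighted over years,
    area-weighted over boxes."""
    wide = traj.pivot(variable)
    y0, y1 = year_range
    sel = wide.loc[(wide.index >= y0) & (wide.index <= y1)]
    if sel.empty:
        raise SelectionError(f"no years in [{y0}, {y1}]")
    boxes = boxes if boxes is not None else list(sel.columns)
    if not boxes:
        raise SelectionError("empty box selection")
    missing = set(boxes) - set(sel.columns)
    if missing:
        raise SelectionError(f"boxes not in trajectory: {sorted(missing)}")
    w = _area_weights(traj, boxes)
    per_box = sel[boxes].mean(axis=0).to_numpy()
    return float(np.dot(per_box, w))


def sector_gradient(
    traj: Trajectory,
    delta_variable: str,
    year_range: tuple[int, int] | None = None,
    per_year: bool = False,
) -> float | pd.Series:
    """Pacific-influenced minus Atlantic-sector mean of a delta variable.

    Area-weighted within each sector; returns a per-year series or the mean
    over a year range.  Only defined for δ variables.
    """
    if delta_variable not in DELTA_VARIABLES:
        raise SelectionError(
            f"sector gradient is defined for {DELTA_VARIABLES}, got {delta_variable!r}"
        )
    pac = traj.boxes_in_sector("pacific_influenced")
    atl = traj.boxes_in_sector("atlantic_sector")
    if not pac or not atl:
        raise SelectionError("both sectors must be populated")
    wide = traj.pivot(delta_variable)
    w_pac = _area_weights(traj, pac)
    w_atl = _area_weights(traj, atl)
    series = wide[pac].to_numpy() @ w_pac - wide[atl].to_numpy() @ w_atl
    series = pd.Series(series, index=wide.index, name=f"gradient_{delta_variable}")
    if year_range is not None:
        y0, y1 = year_range
        series = series.loc[(series.index >= y0) & (series.index <= y1)]
        if series.empty:
            raise SelectionError(f"no years in [{y0}, {y1}]")
    return series if per_year else float(series.mean())


def linear_trend(values, years=None) -> float:
    """Ordinary least-squares slope of an annual series, per decade."""
    y = np.asarray(values, dtype=float)
    if len(y) < 3:
        raise SelectionError("linear trend requires at least 3 points")
    x = np.asarray(years, dtype=float) if years is not None else np.arange(len(y), dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope * 10.0)


def summary_table(traj: Trajectory,
                  periods: list[tuple[int, int]]) -> pd.DataFrame:
    """Headline metrics as a flat (metric, variable, period, value) table."""
    rows = []
    for y0, y1 in periods:
        label = f"{y0}-{y1}"
        for var in ("no3", "pon", "d15n_no3", "d15n_pom", "salinity", "nstar", "ice"):
            rows.append(("decadal_mean", var, label,
                         decadal_mean(traj, var, (y0, y1))))
        for var in DELTA_VARIABLES:
            rows.append(("sector_gradient", var, label,
                         sector_gradient(traj, var, (y0, y1))))
    years = traj.years
    full = (int(years.min()), int(years.max()))
    for var in DELTA_VARIABLES + ("pon", "no3"):
        series = [decadal_mean(traj, var, (y, y)) for y in years]
        rows.append(("trend_per_decade", var, f"{full[0]}-{full[1]}",
                     linear_trend(series, years)))
    return pd.DataFrame(rows, columns=["metric", "variable", "period", "value"])
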