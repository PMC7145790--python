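"""Population-weighted aggregation of point/grid exposures to areal units.

Exposure surfaces usually arrive at finer resolution than the areal units of
analysis; the standard ecological construction weights each location's value
by the resident population it represents.  This module implements the
weighted mean, the "percent of population meeting a standard" variant, and
national decile coding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["population_weighted_mean", "percent_population_meeting", "decile_code"]


def _validate_points(points: pd.DataFrame) -> pd.DataFrame:
    required = {"area_id", "value", "weight"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    if (points["weight"] < 0).any():
        raise ValueError("weights must be non-negative")
    return points


def population_weighted_mean(points: pd.DataFrame) -> pd.Series:
    """Per-area population-weighted mean: sum(w x) / sum(w).

    ``points`` has columns ``area_id``, ``value``, ``weight``.  Areas whose
    total weight is zero come back as NaN with a logged warning.
    """
    points = _validate_points(points)
    wx = points.groupby("area_id").apply(
        lambda g: np.average(g["value"], weights=g["weight"]) if g["weight"].sum() > 0 else np.nan,
        include_groups=False,
    )
    n_missing = int(wx.isna().sum())
    if n_missing:
        log.warning("%d area(s) have zero total weight; reported as missing", n_missing)
    wx.name = "value"
    return wx


def percent_population_meeting(points: pd.DataFrame, indicator: pd.Series | np.ndarray) -> pd.Series:
    """Percent of each area's (weighted) population meeting a criterion.

    ``indicator`` is boolean per record; the result is
    100 * sum(w * 1[indicator]) / sum(w), in [0, 100].
    """
    points = _validate_points(points)
    ind = np.asarray(indicator, dtype=bool)
    if ind.shape[0] != len(points):
        raise ValueError("indicator must have one entry per record")
    tmp = points.assign(value=ind.astype(float))
    pct = 100.0 * population_weighted_mean(tmp)
    pct.name = "percent"
    return pct


def decile_code(values: pd.Series) -> pd.Series:
    """Code area values into national deciles 1..10 (min-tie rule).

    Deciles are over the distribution of non-missing area values; tied
    values all receive the lowest applicable decile, which makes the coding
    deterministic and independent of input order.  Missing values stay
    missing.  Requires at least 10 non-missing areas.
    """
    values = pd.Series(values)
    ok = values.dropna()
    if len(ok) < 10:
        raise ValueError("decile coding requires at least 10 non-missing areas")
    rank_min = ok.rank(method="min")
    dec = np.floor(10.0 * (rank_min - 1) / len(ok)).astype(int) + 1
    out = pd.Series(np.nan, index=values.index, name="decile")
    out.loc[ok.index] = dec
    return out
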