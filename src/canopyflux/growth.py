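"""Log-quadratic canopy growth curves.

Rosette expansion over the short crop cycle is close to exponential with a
slowly declining relative growth rate, which a quadratic in time on the
log scale captures well:

    ln PCS(t) = a + b*t + c*t**2,   t in days after germination.

The curve is fitted per plant by ordinary least squares to the imaged
time points and then evaluated at every integer day — including
back-extrapolation to day 0 — to supply the daily canopy area that the
incident-light budget integrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "fit_log_quadratic",
    "predict_daily_pcs",
    "fit_growth_curves",
    "daily_pcs_table",
]

#: floor applied to back-extrapolated predictions (cm^2); bounds
#: extrapolation pathology while staying far below any real seedling
PCS_FLOOR_CM2 = 0.01

GROWTH_CURVE_COLUMNS = ["plant_id", "a", "b", "c", "r_squared", "day_first", "day_last"]
DAILY_PCS_COLUMNS = ["plant_id", "day", "pcs_cm2"]


@dataclass(frozen=True)
class GrowthCurve:
    """Fitted ``ln PCS = a + b t + c t**2`` with its log-scale R^2."""

    plant_id: int | None
    a: float
    b: float
    c: float
    r_squared: float
    fit_window: tuple[float, float]

    def predict(self, days: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(days, dtype=float)
        out = np.exp(self.a + self.b * t + self.c * t**2)
        return np.maximum(out, PCS_FLOOR_CM2)


def fit_log_quadratic(
    days: np.ndarray,
    pcs_cm2: np.ndarray,
    plant_id: int | None = None,
    r2_warn: float = 0.99,
) -> GrowthCurve:
    """Least-squares fit of the log-quadratic growth law to one series.

    Requires at least three distinct days and strictly positive areas.
    With exactly three distinct days the fit interpolates the data.  A
    log-scale R^2 below ``r2_warn`` raises a warning (not an error): for
    well-behaved rosette growth the fit quality should exceed 0.99.
    """
    t = np.asarray(days, dtype=float)
    y_raw = np.asarray(pcs_cm2, dtype=float)
    if t.shape != y_raw.shape or t.ndim != 1:
        raise ValueError("days and pcs_cm2 must be 1-D and congruent")
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct days to fit a quadratic")
    if np.any(y_raw <= 0):
        raise ValueError("pcs_cm2 must be strictly positive (log is taken)")
    y = np.log(y_raw)
    X = np.column_stack([np.ones_like(t), t, t**2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r2 = 1.0 if np.allclose(resid, 0.0, atol=1e-10) else 0.0
    else:
        r2 = 1.0 - ssr / sst
    if r2 < r2_warn:
        warnings.warn(
            f"plant {plant_id}: growth-curve R^2 = {r2:.4f} below {r2_warn}",
            stacklevel=2,
        )
    return GrowthCurve(
        plant_id=plant_id,
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        r_squared=float(r2),
        fit_window=(float(t.min()), float(t.max())),
    )


def predict_daily_pcs(curve: GrowthCurve, days: np.ndarray) -> pd.DataFrame:
    """Evaluate a fitted curve at integer days (floored at PCS_FLOOR_CM2)."""
    t = np.asarray(days)
    if np.any(t < 0):
        raise ValueError("days must be >= 0 (days after germination)")
    return pd.DataFrame(
        {
            "plant_id": curve.plant_id,
            "day": t,
            "pcs_cm2": curve.predict(t),
        }
    )


def fit_growth_curves(pcs_series: pd.DataFrame, r2_warn: float = 0.99) -> pd.DataFrame:
    """Fit one curve per plant from a PCS series table.

    Expects columns ``plant_id, day, pcs_cm2``; returns the growth-curve
    table (one row per plant).
    """
    rows = []
    for plant_id, grp in pcs_series.groupby("plant_id", sort=True):
        curve = fit_log_quadratic(
            grp["day"].to_numpy(), grp["pcs_cm2"].to_numpy(), plant_id=plant_id, r2_warn=r2_warn
        )
        rows.append(
            (plant_id, curve.a, curve.b, curve.c, curve.r_squared, *curve.fit_window)
        )
    return pd.DataFrame(rows, columns=GROWTH_CURVE_COLUMNS)


def daily_pcs_table(
    curves: pd.DataFrame,
    last_day: pd.Series | dict | int,
    first_day: int = 0,
) -> pd.DataFrame:
    """Daily PCS predictions for every plant from germination onwards.

    ``last_day`` is either a single day or a per-plant mapping (e.g. the
    harvest day); predictions run over ``[first_day, last_day]`` inclusive.
    """
    if isinstance(last_day, pd.Series):
        last = last_day.to_dict()
    elif isinstance(last_day, dict):
        last = last_day
    else:
        last = {pid: int(last_day) for pid in curves["plant_id"]}
    out = []
    for row in curves.itertuples(index=False):
        curve = GrowthCurve(
            plant_id=row.plant_id,
            a=row.a,
            b=row.b,
            c=row.c,
            r_squared=row.r_squared,
            fit_window=(row.day_first, row.day_last),
        )
        days = np.arange(first_day, int(last[row.plant_id]) + 1)
        out.append(predict_daily_pcs(curve, days))
    return pd.concat(out, ignore_index=True)
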