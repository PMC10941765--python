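"""Pre/post-intervention change summaries and forecast-baseline error metrics.

The central quantity is the signed rate of change of a post-period value
against the mean of the pre-period annual values,

    rate = 100 * (post - mean(pre)) / mean(pre),

computed on unrounded totals and rounded to one decimal only when rendered.
A zero pre-period mean with a positive post value has no defined rate and
is reported as NA (this occurs for diseases first appearing in the post
year).  A seasonal-naive forecaster (value twelve months earlier) provides
a transparent baseline for the error metrics MAD, MAPE and RMSE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .tables import MonthlyCaseTable, ROUTES
from .index import NDOISeries, annual_ndoi_means


def rate_of_change(pre: Sequence[float], post: float) -> float:
    """Signed percent change of ``post`` vs the mean of ``pre`` annual values.

    Returns NaN (rendered "NA") when the pre-period mean is zero.
    """
    pre = np.asarray(pre, dtype=float)
    if pre.size == 0:
        raise ValueError("pre-period values must be non-empty")
    base = pre.mean()
    if base == 0:
        return math.nan
    return 100.0 * (float(post) - base) / base


@dataclass
class ChangeReport:
    """Per-item pre/post comparison.

    ``frame`` has one row per item with columns ``item, kind, route``, one
    column per annual value, ``pre_mean``, ``post`` and ``rate_pct`` (NaN
    where undefined).
    """

    frame: pd.DataFrame
    pre_years: tuple[int, ...]
    post_year: int

    def rendered(self) -> pd.DataFrame:
        """Display form: one-decimal rates, NaN shown as 'NA'."""
        out = self.frame.copy()
        out["rate_pct"] = out["rate_pct"].map(lambda v: "NA" if pd.isna(v) else f"{v:.1f}")
        return out


def _report_row(item: str, kind: str, route, annual: Mapping[int, float],
                pre_years: Sequence[int], post_year: int) -> dict:
    pre_vals = [annual[y] for y in pre_years]
    post = annual[post_year]
    row = {"item": item, "kind": kind, "route": route}
    row.update({f"y{y}": annual[y] for y in (*pre_years, post_year)})
    row["pre_mean"] = float(np.mean(pre_vals))
    row["post"] = float(post)
    row["rate_pct"] = rate_of_change(pre_vals, post)
    return row


def build_change_report(table: MonthlyCaseTable,
                        ndoi_by_stratum: Mapping[str, NDOISeries] | None = None,
                        pre_years: Sequence[int] = (2017, 2018, 2019),
                        post_year: int = 2020) -> ChangeReport:
    """Annual-change report: one row per disease, per route aggregate, and overall.

    Annual totals are calendar-year sums of the monthly counts.  When NDOI
    series are supplied (keyed by stratum), their annual means are compared
    the same way, mirroring the published summary-table layout.
    """
    years = set(table.months.year)
    missing = [y for y in (*pre_years, post_year) if y not in years]
    if missing:
        raise ValueError(f"table does not cover years {missing}")
    annual_counts = table.counts.groupby(table.months.year).sum()
    rows = []
    all_annual = annual_counts.sum(axis=1)
    rows.append(_report_row("All diseases", "all_cases", None,
                            all_annual.to_dict(), pre_years, post_year))
    for route in ROUTES:
        cols = table.catalog.diseases_in_route(route)
        if not cols:
            continue
        route_annual = annual_counts[list(cols)].sum(axis=1)
        rows.append(_report_row(f"{route} route", "route_cases", route,
                                route_annual.to_dict(), pre_years, post_year))
        for disease in cols:
            rows.append(_report_row(disease, "disease", route,
                                    annual_counts[disease].to_dict(), pre_years, post_year))
    for stratum, series in (ndoi_by_stratum or {}).items():
        means = annual_ndoi_means(series, allow_partial=True)
        kind = "all_ndoi" if stratum == "all" else "route_ndoi"
        route = None if stratum == "all" else stratum
        rows.append(_report_row(f"NDOI ({stratum})", kind, route,
                                means.to_dict(), pre_years, post_year))
    return ChangeReport(pd.DataFrame(rows), tuple(pre_years), post_year)


class SeasonalNaiveForecaster(BaseEstimator, RegressorMixin):
    """Seasonal-naive baseline: each month repeats its value one year earlier.

    Serves as the package's transparent forecast baseline for monthly
    surveillance series; ``fit`` memorizes the history, ``predict(horizon)``
    walks forward month by month re-using the value 12 steps back.
    """

    period = 12

    def fit(self, y: Sequence[float], X=None):
        y = np.asarray(y, dtype=float)
        if y.size < self.period:
            raise ValueError(f"need at least {self.period} observations, got {y.size}")
        self.history_ = y
        return self

    def predict(self, horizon: int) -> np.ndarray:
        if horizon <= 0:
            raise ValueError("horizon must be a positive number of months")
        buf = list(self.history_)
        out = []
        for _ in range(int(horizon)):
            out.append(buf[-self.period])
            buf.append(buf[-self.period])
        return np.asarray(out)


def seasonal_naive_forecast(series: Sequence[float], horizon: int) -> np.ndarray:
    """Thin wrapper over :class:`SeasonalNaiveForecaster`."""
    return SeasonalNaiveForecaster().fit(series).predict(horizon)


def forecast_errors(observed: Sequence[float], predicted: Sequence[float]) -> dict[str, float]:
    """MAD, MAPE (%) and RMSE of a forecast against observations.

    MAPE is NaN (with a warning) when any observed value is zero.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    err = o - p
    mad = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.any(o == 0):
        warnings.warn("observed series contains zeros; MAPE undefined, reported as NaN",
                      UserWarning, stacklevel=2)
        mape = math.nan
    else:
        mape = float(100.0 * np.mean(np.abs(err) / np.abs(o)))
    return {"MAD": mad, "MAPE": mape, "RMSE": rmse}
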