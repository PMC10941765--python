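"""Packaged reference data: Shanghai 2017–2020 annual notifiable-disease summary.

The packaged fixture carries, verbatim as printed, the annual confirmed-case
totals for 32 notifiable diseases grouped by four transmission routes, the
per-route annual case and NDOI aggregates, the all-disease annual totals and
annual-mean NDOI values, and the published three-year averages and signed
rates of change.  One printed cell (hand-foot-and-mouth disease, 2019) is
stored as 24,788: the source prints "247,88", a typesetting artifact, and the
printed three-year mean 34,019 forces the corrected value.

Printed averages and rates are display-rounded; analyses should recompute
them from the annual totals (see :mod:`ndoikit.change`) and may use the
printed columns to audit agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tables import ROUTES, DiseaseCatalog

PRE_YEARS: tuple[int, ...] = (2017, 2018, 2019)
POST_YEAR: int = 2020
_YEAR_COLS = ["y2017", "y2018", "y2019", "y2020"]


@dataclass(frozen=True)
class AnnualSummaryTable:
    """Annual case totals and NDOI aggregates by disease and route.

    ``frame`` has one row per item with columns ``item, kind, route,
    y2017..y2020, printed_average, printed_rate_pct``; ``kind`` is one of
    ``disease``, ``route_cases``, ``route_ndoi``, ``all_cases``,
    ``all_ndoi``.
    """

    frame: pd.DataFrame

    def _one(self, mask) -> pd.Series:
        sub = self.frame[mask]
        if len(sub) != 1:
            raise KeyError("fixture query did not match exactly one row")
        return sub.iloc[0]

    def _annual(self, row: pd.Series) -> dict[int, float]:
        return {int(c[1:]): float(row[c]) for c in _YEAR_COLS}

    def disease_annual(self, disease: str) -> dict[int, float]:
        """Annual case totals {year: cases} for one disease."""
        return self._annual(self._one((self.frame.kind == "disease") & (self.frame.item == disease)))

    def route_cases(self, route: str) -> dict[int, float]:
        return self._annual(self._one((self.frame.kind == "route_cases") & (self.frame.route == route)))

    def route_ndoi(self, route: str) -> dict[int, float]:
        return self._annual(self._one((self.frame.kind == "route_ndoi") & (self.frame.route == route)))

    def all_cases(self) -> dict[int, float]:
        return self._annual(self._one(self.frame.kind == "all_cases"))

    def all_ndoi(self) -> dict[int, float]:
        return self._annual(self._one(self.frame.kind == "all_ndoi"))

    def printed_rate(self, item: str) -> float:
        """Printed signed rate of change (%); NaN where printed as NA."""
        rows = self.frame[self.frame.item == item]
        if len(rows) != 1:
            raise KeyError(f"ambiguous or missing item {item!r}; use kind-specific accessors")
        return float(rows.iloc[0].printed_rate_pct)

    def printed_mean(self, item: str, kind: str = "disease") -> float:
        return float(self._one((self.frame.kind == kind) & (self.frame.item == item)).printed_average)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.frame[self.frame.kind == "disease"].item)

    def catalog(self) -> DiseaseCatalog:
        sub = self.frame[self.frame.kind == "disease"]
        return DiseaseCatalog(list(zip(sub.item, sub.route)))

    def pre_mean(self, annual: dict[int, float]) -> float:
        """Arithmetic mean of the pre-period (2017–2019) annual values."""
        return float(np.mean([annual[y] for y in PRE_YEARS]))


def load_table2() -> AnnualSummaryTable:
    """Load the packaged Shanghai 2017–2020 annual summary."""
    with resources.files("ndoikit.data").joinpath("shanghai_table2.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, na_values=["NA"], keep_default_na=False)
    frame["route"] = frame["route"].replace("", np.nan)
    for route in ROUTES:
        assert (frame.route == route).any()
    return AnnualSummaryTable(frame)
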