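"""Surveillance-table domain types and tabular I/O.

The package's inputs are monthly notifiable-disease report tables: a
months × diseases matrix of confirmed-case counts together with a catalog
assigning each disease to one of four transmission routes, plus a
months × factors matrix of environmental / socioeconomic covariates.
Months are represented internally as pandas ``Period`` objects with
monthly frequency and serialized as ``YYYY-MM`` text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four transmission-route strata used throughout the package.
ROUTES: tuple[str, ...] = ("direct-contact", "water-food", "airborne", "vector-borne")


class ValidationError(ValueError):
    """A table violated a structural invariant (named row/column in message)."""


class CatalogError(ValueError):
    """A disease catalog entry is malformed or a route is unknown."""


class AlignmentError(ValueError):
    """Two tables do not share the month range an operation requires."""


@dataclass(frozen=True)
class DiseaseCatalog:
    """Maps disease names to transmission routes.

    Parameters
    ----------
    entries : sequence of (name, route)
        Disease names must be unique and non-empty; every route must be one
        of :data:`ROUTES`.
    """

    entries: tuple[tuple[str, str], ...]

    def __init__(self, entries: Iterable[tuple[str, str]] | Mapping[str, str]):
        if isinstance(entries, Mapping):
            entries = tuple(entries.items())
        else:
            entries = tuple((str(n), str(r)) for n, r in entries)
        names = [n for n, _ in entries]
        if any(not n for n in names):
            raise CatalogError("disease names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"duplicate disease names: {dupes}")
        for n, r in entries:
            if r not in ROUTES:
                raise CatalogError(f"unknown transmission route {r!r} for disease {n!r}; expected one of {ROUTES}")
        object.__setattr__(self, "entries", entries)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def route_of(self, disease: str) -> str:
        for n, r in self.entries:
            if n == disease:
                return r
        raise CatalogError(f"disease {disease!r} not in catalog")

    def diseases_in_route(self, route: str) -> tuple[str, ...]:
        if route not in ROUTES:
            raise CatalogError(f"unknown transmission route {route!r}")
        return tuple(n for n, r in self.entries if r == route)

    def subset(self, diseases: Sequence[str]) -> "DiseaseCatalog":
        keep = set(diseases)
        return DiseaseCatalog(tuple((n, r) for n, r in self.entries if n in keep))


def _as_month_index(months: Iterable) -> pd.PeriodIndex:
    idx = pd.PeriodIndex([pd.Period(m, freq="M") for m in months], freq="M")
    if idx.has_duplicates:
        raise ValidationError("duplicate months in table")
    return idx


@dataclass
class MonthlyCaseTable:
    """A months × diseases matrix of non-negative integer case counts.

    ``counts`` is a DataFrame indexed by a monthly ``PeriodIndex`` whose
    column set equals the catalog's disease set; rows are kept sorted
    ascending by month.
    """

    counts: pd.DataFrame
    catalog: DiseaseCatalog

    def __post_init__(self) -> None:
        df = self.counts.copy()
        df.index = _as_month_index(df.index)
        df = df.sort_index()
        if set(df.columns) != set(self.catalog.diseases):
            missing = set(self.catalog.diseases) - set(df.columns)
            extra = set(df.columns) - set(self.catalog.diseases)
            raise ValidationError(f"column/catalog mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        df = df[list(self.catalog.diseases)]
        arr = df.to_numpy()
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValidationError("non-finite count present")
        frac, _ = np.modf(arr.astype(float))
        if np.any(frac != 0):
            r, c = np.argwhere(frac != 0)[0]
            raise ValidationError(f"non-integer count at month {df.index[r]}, disease {df.columns[c]!r}")
        if np.any(arr.astype(float) < 0):
            r, c = np.argwhere(arr.astype(float) < 0)[0]
            raise ValidationError(f"negative count at month {df.index[r]}, disease {df.columns[c]!r}")
        self.counts = df.astype(np.int64)

    @property
    def months(self) -> pd.PeriodIndex:
        return self.counts.index

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    def route_columns(self, route: str) -> pd.DataFrame:
        return self.counts[list(self.catalog.diseases_in_route(route))]

    def restrict_years(self, years: Sequence[int]) -> "MonthlyCaseTable":
        mask = self.months.year.isin(list(years))
        return MonthlyCaseTable(self.counts.loc[mask], self.catalog)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MonthlyCaseTable)
            and self.counts.equals(other.counts)
            and self.catalog == other.catalog
        )


@dataclass
class CovariateTable:
    """A months × factors matrix of real-valued indicators.

    Missing values are rejected on construction unless ``interpolate`` was
    requested at load time (linear interpolation over months); units are
    free-text metadata keyed by factor name.
    """

    values: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.index = _as_month_index(df.index)
        df = df.sort_index().astype(float)
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            raise ValidationError(f"missing value in covariate column {col!r} (load with interpolation to fill)")
        self.values = df

    @property
    def months(self) -> pd.PeriodIndex:
        return self.values.index

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


# ---------------------------------------------------------------------------
# CSV I/O.  Format: first column "month" holding YYYY-MM, one column per
# disease/factor, UTF-8, comma-separated.  The route map travels either in a
# second header row ("#route,...") or as a separate mapping argument.
# ---------------------------------------------------------------------------

def write_case_table(table: MonthlyCaseTable, path: str | Path) -> None:
    """Write a case table as CSV with a ``#route`` comment row.

    Output is deterministic for a fixed table: columns in catalog order,
    months ascending as ``YYYY-MM``.
    """
    path = Path(path)
    routes = [table.catalog.route_of(d) for d in table.diseases]
    lines = ["month," + ",".join(table.diseases) if table.diseases else "month"]
    lines.append("#route," + ",".join(routes) if routes else "#route")
    for month, row in table.counts.iterrows():
        lines.append(str(month) + "," + ",".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_case_table(path: str | Path, route_map: Mapping[str, str] | None = None) -> MonthlyCaseTable:
    """Read a case-table CSV written by :func:`write_case_table`.

    ``route_map`` overrides / replaces an embedded ``#route`` row; one of
    the two must supply a route for every disease column.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = lines[0].split(",")
    diseases = header[1:]
    embedded: dict[str, str] = {}
    data_lines = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        if ln.startswith("#route"):
            routes = ln.split(",")[1:]
            embedded = dict(zip(diseases, routes))
        else:
            data_lines.append(ln)
    routes_final = dict(embedded)
    if route_map:
        routes_final.update(route_map)
    missing = [d for d in diseases if d not in routes_final]
    if missing:
        raise CatalogError(f"no transmission route supplied for columns {missing}")
    months, rows = [], []
    for ln in data_lines:
        parts = ln.split(",")
        months.append(parts[0])
        vals = []
        for d, tok in zip(diseases, parts[1:]):
            try:
                v = float(tok)
            except ValueError as exc:
                raise ValidationError(f"{path}: non-numeric count {tok!r} in month {parts[0]}, disease {d!r}") from exc
            vals.append(v)
        rows.append(vals)
    catalog = DiseaseCatalog([(d, routes_final[d]) for d in diseases])
    df = pd.DataFrame(rows, index=months, columns=diseases)
    return MonthlyCaseTable(df, catalog)


def write_covariate_table(table: CovariateTable, path: str | Path) -> None:
    path = Path(path)
    lines = ["month," + ",".join(table.factors) if table.factors else "month"]
    for month, row in table.values.iterrows():
        lines.append(str(month) + "," + ",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_covariate_table(path: str | Path, interpolate: bool = False,
                         units: Mapping[str, str] | None = None) -> CovariateTable:
    """Read a covariate CSV; ``interpolate=True`` fills gaps linearly over months."""
    df = pd.read_csv(path, index_col=0)
    df.index = _as_month_index(df.index)
    df = df.sort_index().astype(float)
    if interpolate:
        df = df.interpolate(method="linear", limit_direction="both")
    return CovariateTable(df, dict(units or {}))
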