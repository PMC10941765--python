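"""The index of notifiable disease outbreaks (NDOI).

For a period (month) *i* within a chosen stratum (all diseases, or one
transmission route), let ``n_i`` be the total confirmed cases summed over
the stratum's diseases and ``t_i`` the number of distinct diseases with at
least one case.  Both series are min–max normalized over the analysis
window to ``N_i``, ``T_i`` in [0, 1], and the index is their convex
combination

    NDOI_i = alpha * N_i + beta * T_i,      alpha + beta = 1,

so the index itself lies in [0, 1]: 1 in the month attaining both window
maxima, 0 at both minima.  The weights are either fixed (e.g. the published
Shanghai calibration alpha = 0.51, beta = 0.49) or derived from the data by
the entropy weight method, which gives more weight to the indicator with
lower Shannon entropy (more dispersion) across months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import MonthlyCaseTable, ROUTES

#: Entropy weights published for the Shanghai 2017–2020 monthly series.
SHANGHAI_WEIGHTS: tuple[float, float] = (0.51, 0.49)


class DegenerateSeriesWarning(UserWarning):
    """Min–max normalization hit max == min; values were set to 0."""


class WeightError(ValueError):
    """Entropy weights are undefined for this input."""


class StratumError(KeyError):
    """Requested stratum is not 'all' or a catalog route."""


@dataclass(frozen=True)
class NormalizedSeries:
    """A min–max normalized series with its source range."""

    values: np.ndarray
    source_min: float
    source_max: float
    degenerate: bool = False


@dataclass(frozen=True)
class EntropyWeights:
    """The (alpha, beta) weight pair; alpha weighs cases, beta weighs types."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise WeightError("weights must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise WeightError(f"weights must sum to 1, got {self.alpha + self.beta}")


def minmax_normalize(series) -> NormalizedSeries:
    """Rescale a series linearly to [0, 1] by its observed range.

    A constant series (max == min) carries no outbreak signal: all values
    are mapped to 0 and the result is flagged degenerate.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant series: min–max range is degenerate, returning zeros",
                      DegenerateSeriesWarning, stacklevel=2)
        return NormalizedSeries(np.zeros_like(x), lo, hi, degenerate=True)
    return NormalizedSeries((x - lo) / (hi - lo), lo, hi)


def monthly_components(table: MonthlyCaseTable, stratum: str = "all") -> pd.DataFrame:
    """Per-month case total ``n`` and type count ``t`` for a stratum.

    ``t`` counts the stratum's diseases reporting at least one case in the
    month ("types of disease present").
    """
    if stratum == "all":
        sub = table.counts
    elif stratum in ROUTES:
        sub = table.route_columns(stratum)
    else:
        raise StratumError(f"stratum must be 'all' or one of {ROUTES}, got {stratum!r}")
    return pd.DataFrame({"n": sub.sum(axis=1), "t": (sub >= 1).sum(axis=1)}, index=table.months)


def entropy_weights(components: pd.DataFrame) -> EntropyWeights:
    """Entropy-weight coefficients for the (cases, types) indicator pair.

    Standard recipe on the min–max-normalized indicator columns ``x``
    (m months × 2 indicators): shares ``p_ij = x_ij / sum_i x_ij``, entropy
    ``e_j = -(1/ln m) * sum_i p_ij ln p_ij`` (with 0·ln 0 := 0), divergence
    ``d_j = 1 - e_j``, weights ``w_j = d_j / sum_j d_j``.  The less uniform
    indicator (lower entropy) receives the larger weight.
    """
    if len(components) < 2:
        raise WeightError("entropy weights need at least 2 months")
    m = len(components)
    cols = []
    for name in ("n", "t"):
        norm = minmax_normalize(components[name].to_numpy())
        col = norm.values
        total = col.sum()
        if total <= 0:
            raise WeightError(f"indicator {name!r} is all zero after normalization; entropy undefined")
        cols.append(col / total)
    d = []
    for p in cols:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum() / np.log(m)
        d.append(1.0 - e)
    d = np.asarray(d)
    if d.sum() <= 0:
        raise WeightError("both indicators are maximally uniform; entropy weights undefined")
    w = d / d.sum()
    return EntropyWeights(float(w[0]), float(w[1]))


@dataclass
class NDOISeries:
    """Monthly NDOI values with their underlying components.

    ``frame`` holds per-month columns ``n, t, N, T, ndoi``; ``stratum`` is
    "all" or a transmission route; ``weights`` is the (alpha, beta) pair
    actually applied.
    """

    frame: pd.DataFrame
    stratum: str
    weights: EntropyWeights

    @property
    def ndoi(self) -> pd.Series:
        return self.frame["ndoi"]

    @property
    def months(self) -> pd.PeriodIndex:
        return self.frame.index


class EntropyWeightNDOI(BaseEstimator, TransformerMixin):
    """Entropy-weighted composite outbreak index over monthly case tables.

    Parameters
    ----------
    stratum : "all" or a transmission route
        Which diseases enter the monthly case total and type count.
    weights : "auto" or (alpha, beta)
        "auto" derives the weights from the fitted table by the entropy
        weight method; a fixed pair (e.g. ``SHANGHAI_WEIGHTS``) reproduces a
        published calibration.

    Attributes
    ----------
    weights_ : EntropyWeights
        The applied (alpha, beta) pair.
    n_range_, t_range_ : (min, max)
        Normalization windows learned from the fitted table; transform
        re-uses them so new months are scored on the fitted scale.
    """

    def __init__(self, stratum: str = "all", weights="auto"):
        self.stratum = stratum
        self.weights = weights

    def fit(self, X: MonthlyCaseTable, y=None):
        comps = monthly_components(X, self.stratum)
        if self.weights == "auto":
            self.weights_ = entropy_weights(comps)
        else:
            alpha, beta = self.weights
            self.weights_ = EntropyWeights(float(alpha), float(beta))
        self.n_range_ = (float(comps["n"].min()), float(comps["n"].max()))
        self.t_range_ = (float(comps["t"].min()), float(comps["t"].max()))
        return self

    def _normalize(self, values: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
        lo, hi = rng
        if hi == lo:
            warnings.warn("degenerate normalization window, component set to 0",
                          DegenerateSeriesWarning, stacklevel=2)
            return np.zeros(len(values))
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)

    def transform(self, X: MonthlyCaseTable) -> NDOISeries:
        comps = monthly_components(X, self.stratum)
        N = self._normalize(comps["n"].to_numpy(), self.n_range_)
        T = self._normalize(comps["t"].to_numpy(), self.t_range_)
        w = self.weights_
        frame = comps.assign(N=N, T=T, ndoi=w.alpha * N + w.beta * T)
        return NDOISeries(frame, self.stratum, w)


def compute_ndoi(table: MonthlyCaseTable, stratum: str = "all", weights="auto") -> NDOISeries:
    """Fit-and-transform convenience wrapper around :class:`EntropyWeightNDOI`."""
    return EntropyWeightNDOI(stratum=stratum, weights=weights).fit(table).transform(table)


def annual_ndoi_means(series: NDOISeries, allow_partial: bool = False) -> pd.Series:
    """Calendar-year arithmetic means of the monthly NDOI values."""
    years = series.months.year
    counts = pd.Series(1, index=series.months).groupby(years).sum()
    if not allow_partial and (counts != 12).any():
        bad = counts[counts != 12].index.tolist()
        raise ValueError(f"partial calendar years {bad}; pass allow_partial=True to average anyway")
    return series.ndoi.groupby(years).mean()
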