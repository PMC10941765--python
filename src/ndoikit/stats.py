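"""Univariate screening statistics for monthly surveillance series.

Normality is screened with a moment-matched one-sample Kolmogorov–Smirnov
test (the sample is compared to a normal with its own mean and SD, the
convention of mainstream desktop statistics packages; slightly
anti-conservative relative to a Lilliefors correction).  Series failing the
screen are log10(x+1)-transformed, the offset admitting zero counts.
Period contrasts use classical one-way ANOVA, and disease–factor
associations use pairwise Pearson correlation with two-sided p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import CovariateTable, MonthlyCaseTable


def ks_normality(series, alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample KS test of a series against a moment-matched normal.

    Returns ``(D, p, is_normal)`` where ``is_normal`` is ``p >= alpha``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("KS normality screen needs at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series: normality is undefined")
    z = (x - x.mean()) / sd
    res = sps.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue >= alpha)


def log_transform_if_needed(series, alpha: float = 0.05) -> tuple[np.ndarray, bool]:
    """log10(x+1)-transform a non-negative series if it fails the KS screen.

    Returns the (possibly transformed) series and a flag recording whether
    the transform was applied.
    """
    x = np.asarray(series, dtype=float)
    if np.any(x < 0):
        raise ValueError("log transform requires non-negative values")
    _, _, is_normal = ks_normality(x, alpha=alpha)
    if is_normal:
        return x, False
    return np.log10(x + 1.0), True


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over ≥2 groups of ≥2 observations.

    With zero within-group variance and unequal means the F statistic is
    infinite and p is 0 to machine precision.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("one-way ANOVA needs >=2 groups with >=2 observations each")
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = len(arrs) - 1, n_total - len(arrs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson r and two-sided p between diseases and factors."""

    r: pd.DataFrame
    p: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p < alpha


def pearson_matrix(cases: MonthlyCaseTable, covariates: CovariateTable,
                   preprocess: bool = True,
                   bh_correct: bool = False) -> CorrelationMatrix:
    """Disease × factor Pearson correlation matrix on aligned months.

    ``preprocess`` applies :func:`log_transform_if_needed` to each disease
    column (counts are typically right-skewed).  ``bh_correct`` optionally
    applies a Benjamini–Hochberg adjustment across the whole p matrix; the
    default reports raw p-values.
    """
    common = cases.months.intersection(covariates.months)
    if len(common) < 3:
        raise ValueError("fewer than 3 aligned months between cases and covariates")
    case_df = cases.counts.loc[common]
    cov_df = covariates.values.loc[common]
    r = pd.DataFrame(index=case_df.columns, columns=cov_df.columns, dtype=float)
    p = r.copy()
    for disease in case_df.columns:
        y = case_df[disease].to_numpy(dtype=float)
        if preprocess and y.std(ddof=1) > 0:
            y, _ = log_transform_if_needed(y)
        for factor in cov_df.columns:
            x = cov_df[factor].to_numpy()
            if y.std() == 0 or x.std() == 0:
                r.loc[disease, factor], p.loc[disease, factor] = math.nan, math.nan
                continue
            res = sps.pearsonr(x, y)
            r.loc[disease, factor] = float(res.statistic)
            p.loc[disease, factor] = float(res.pvalue)
    if bh_correct:
        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, math.nan)
        adj[ok] = sps.false_discovery_control(flat[ok], method="bh")
        p = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return CorrelationMatrix(r, p)
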