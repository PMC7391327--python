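"""Weighted survival aggregation, trend tests and between-site correlations.

Site-year survival proportions are combined with weights equal to the number
of pups observed, so populous beaches contribute in proportion to the seals
actually there. The module also provides the ordinary least-squares trend
test on the annual weighted means and the pairwise Pearson diagnostics that
quantify how (weakly) synchronised temporal variation is across sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SiteYearRecord, SurvivalDataset

__all__ = [
    "AggregateSeries",
    "TrendFit",
    "CorrelationSummary",
    "weighted_mean_survival",
    "area_year_series",
    "overall_mean_survival",
    "trend_test",
    "pairwise_site_correlations",
]


@dataclass(frozen=True)
class AggregateSeries:
    """Pup-weighted mean survival for one sampling area in one year."""

    area_id: str
    year: int
    mean_survival: float
    total_weight: float
    n_sites: int


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an annual survival series against calendar year."""

    slope: float
    intercept: float
    F: float
    df1: int
    df2: int
    p_value: float
    r2: float


@dataclass(frozen=True)
class CorrelationSummary:
    """Summary of pairwise Pearson correlations between site survival series."""

    mean_r: float
    sem_r: float
    mean_p: float
    n_pairs: int
    min_overlap: int
    n_skipped_degenerate: int = 0


def weighted_mean_survival(
    records: Sequence[SiteYearRecord], weight_field: str = "n_pups"
) -> float:
    """Weighted arithmetic mean of survival over records.

    Weights default to the corrected pup count, so each record contributes in
    proportion to the animals observed.
    """
    if not records:
        raise ValueError("no records to average")
    weights = np.array([getattr(r, weight_field) for r in records], dtype=float)
    if (weights < 0).any():
        raise ValueError("negative weights")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    survs = np.array([r.survival for r in records], dtype=float)
    return float(np.dot(weights, survs) / total)


def overall_mean_survival(
    dataset: SurvivalDataset, weight_field: str = "n_pups"
) -> float:
    """Pooled pup-weighted mean survival over all site-year records."""
    return weighted_mean_survival(dataset.records, weight_field)


def area_year_series(
    dataset: SurvivalDataset, weight_field: str = "n_pups"
) -> list[AggregateSeries]:
    """One weighted-mean entry per (area, year) with at least one record."""
    if not dataset.records:
        raise ValueError("dataset is empty")
    groups: dict[tuple[str, int], list[SiteYearRecord]] = {}
    for r in dataset.records:
        groups.setdefault((r.area_id, r.year), []).append(r)
    out = []
    for (area, year), recs in sorted(groups.items()):
        out.append(
            AggregateSeries(
                area_id=area,
                year=year,
                mean_survival=weighted_mean_survival(recs, weight_field),
                total_weight=float(sum(getattr(r, weight_field) for r in recs)),
                n_sites=len({r.site_id for r in recs}),
            )
        )
    return out


def series_frame(series: Iterable[AggregateSeries]) -> pd.DataFrame:
    """Tidy table (area, year, mean_survival, total_weight, n_sites)."""
    return pd.DataFrame(
        {
            "area": [s.area_id for s in series],
            "year": [s.year for s in series],
            "mean_survival": [s.mean_survival for s in series],
            "total_weight": [s.total_weight for s in series],
            "n_sites": [s.n_sites for s in series],
        }
    )


def trend_test(series: Sequence[AggregateSeries]) -> TrendFit:
    """Test an annual weighted-mean series for a directional trend.

    Ordinary least squares of mean survival on year; the F statistic is
    (r2/(1-r2)) * df2 with df2 = n - 2, and the p-value is the upper tail of
    F(1, df2). A perfectly constant response gives F = 0, p = 1.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 annual points for a trend test")
    years = np.array([s.year for s in series], dtype=float)
    y = np.array([s.mean_survival for s in series], dtype=float)
    if np.ptp(years) == 0:
        raise ValueError("year has no variance; trend undefined")
    n = len(y)
    df2 = n - 2
    sxx = float(np.sum((years - years.mean()) ** 2))
    sxy = float(np.sum((years - years.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * years.mean())
    if syy == 0:  # constant response: no trend by definition
        return TrendFit(0.0, intercept, 0.0, 1, df2, 1.0, 0.0)
    r2 = sxy**2 / (sxx * syy)
    r2 = min(r2, 1.0)
    if r2 >= 1.0:
        f_stat = math.inf
        p = 0.0
    else:
        f_stat = (r2 / (1.0 - r2)) * df2
        p = float(stats.f.sf(f_stat, 1, df2))
    return TrendFit(slope, intercept, f_stat, 1, df2, p, r2)


def pairwise_site_correlations(
    dataset: SurvivalDataset, min_overlap: int = 5
) -> CorrelationSummary:
    """Mean pairwise Pearson correlation between site survival time series.

    For every unordered site pair sharing at least ``min_overlap`` years,
    the Pearson r (and its exact-t two-sided p, n-2 df) is computed on the
    paired survival series. Pairs where either series is constant over the
    overlap are skipped (r undefined) and counted separately. A mean r near
    zero indicates that temporal ups and downs are site-specific rather than
    shared environmental signal.
    """
    if not dataset.records:
        raise ValueError("dataset is empty")
    by_site: dict[str, dict[int, float]] = {}
    for r in dataset.records:
        by_site.setdefault(r.site_id, {})[r.year] = r.survival
    rs: list[float] = []
    ps: list[float] = []
    n_skipped = 0
    for s1, s2 in combinations(sorted(by_site), 2):
        shared = sorted(set(by_site[s1]) & set(by_site[s2]))
        if len(shared) < min_overlap:
            continue
        x = np.array([by_site[s1][y] for y in shared])
        y = np.array([by_site[s2][y] for y in shared])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_skipped += 1
            continue
        res = stats.pearsonr(x, y)
        rs.append(float(res.statistic))
        ps.append(float(res.pvalue))
    n_pairs = len(rs)
    if n_pairs == 0:
        warnings.warn("no qualifying site pairs; correlation summary undefined")
        return CorrelationSummary(
            math.nan, math.nan, math.nan, 0, min_overlap, n_skipped
        )
    mean_r = float(np.mean(rs))
    sem_r = float(np.std(rs, ddof=1) / math.sqrt(n_pairs)) if n_pairs > 1 else 0.0
    return CorrelationSummary(
        mean_r=mean_r,
        sem_r=sem_r,
        mean_p=float(np.mean(ps)),
        n_pairs=n_pairs,
        min_overlap=min_overlap,
        n_skipped_degenerate=n_skipped,
    )
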