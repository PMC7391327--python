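"""Leave-one-site-out sensitivity and bootstrap sample-size requirements.

Two complementary questions about a patchwork census:

* how much does any single monitored beach pull the overall weighted mean
  survival up or down (leave-one-site-out sensitivity, with follow-up models
  relating the sensitivity to sampling area and to site population size); and
* how many site-year survival estimates must be sampled before the sample
  mean is reliably close to the estimate using all available data (the
  resampled sample-size requirement curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .aggregate import overall_mean_survival
from .data import SurvivalDataset

__all__ = [
    "SensitivityResult",
    "ModelFit",
    "SampleSizeCurve",
    "loo_site_sensitivity",
    "sensitivity_models",
    "sample_size_curve",
    "required_n",
    "NOT_REACHED",
]

#: sentinel returned by required_n when no sample size attains the threshold
NOT_REACHED = -1


@dataclass(frozen=True)
class SensitivityResult:
    """Change in the overall weighted mean when one site is omitted.

    Positive ``delta`` means omitting the site *raises* the estimate, i.e.
    the site drags the mean down while present.
    """

    site_id: str
    area_id: str
    delta: float
    mean_pups: float


@dataclass(frozen=True)
class ModelFit:
    """An F test from a linear model on the sensitivities."""

    model: str
    F: float
    df1: int
    df2: int
    p_value: float
    slope: float | None = None


@dataclass(frozen=True)
class SampleSizeCurve:
    """Proportion of resampled means within tolerance of the target mean."""

    scope: str
    n_values: tuple[int, ...]
    proportion_within: tuple[float, ...]
    tolerance: float
    reps: int
    target_mean: float
    seed: int


def loo_site_sensitivity(
    dataset: SurvivalDataset, weight_field: str = "n_pups"
) -> list[SensitivityResult]:
    """Leave-one-site-out sensitivity of the overall weighted mean survival.

    Expects a dataset already restricted to years in which every sampling
    area is represented (see :func:`sealpup.data.subset_years_all_areas`), so
    that areas with short monitoring histories are comparable.
    """
    if not dataset.records:
        raise ValueError("dataset is empty")
    base = overall_mean_survival(dataset, weight_field)
    out = []
    for site in dataset.sites:
        remaining = dataset.drop_site(site)
        if not remaining.records:
            raise ValueError(f"removing site {site!r} empties the dataset")
        without = overall_mean_survival(remaining, weight_field)
        site_recs = [r for r in dataset.records if r.site_id == site]
        out.append(
            SensitivityResult(
                site_id=site,
                area_id=dataset.nesting[site],
                delta=without - base,
                mean_pups=float(np.mean([r.n_pups for r in site_recs])),
            )
        )
    return out


def sensitivity_models(
    results: Sequence[SensitivityResult],
) -> dict[str, ModelFit]:
    """F tests for area differences and population-size association.

    Fits (i) a one-way model of delta on sampling area — F on
    (n_areas - 1, n_sites - n_areas) df — and (ii) a simple regression of
    delta on the site's mean pup count — F on (1, n_sites - 2) df. Model (i)
    is skipped (with a notice) when only one area is present.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 sites")
    deltas = np.array([r.delta for r in results])
    pups = np.array([r.mean_pups for r in results])
    areas = [r.area_id for r in results]
    fits: dict[str, ModelFit] = {}

    unique_areas = sorted(set(areas))
    if len(unique_areas) < 2:
        warnings.warn("single sampling area; delta ~ area model skipped")
    else:
        groups = [deltas[[a == u for a in areas]] for u in unique_areas]
        n, k = len(deltas), len(unique_areas)
        grand = deltas.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df1, df2 = k - 1, n - k
        if ss_within == 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (ss_between / df1) / (ss_within / df2)
            p = float(stats.f.sf(f_stat, df1, df2))
        fits["delta_by_area"] = ModelFit("delta ~ area", float(f_stat), df1, df2, p)

    n = len(deltas)
    df2 = n - 2
    sxx = float(np.sum((pups - pups.mean()) ** 2))
    if sxx == 0:
        raise ValueError("mean_pups has no variance")
    slope = float(np.sum((pups - pups.mean()) * (deltas - deltas.mean())) / sxx)
    syy = float(np.sum((deltas - deltas.mean()) ** 2))
    if syy == 0:
        f_stat, p = 0.0, 1.0
    else:
        r2 = (slope**2 * sxx) / syy
        if r2 >= 1.0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (r2 / (1 - r2)) * df2
            p = float(stats.f.sf(f_stat, 1, df2))
    fits["delta_by_pups"] = ModelFit(
        "delta ~ mean_pups", float(f_stat), 1, df2, p, slope=slope
    )
    return fits


def _rng_for(seed: int, scope_key: int, n: int) -> np.random.Generator:
    # per-(scope, n) substream: adding an n value never perturbs the others
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(scope_key, n)))


def sample_size_curve(
    dataset: SurvivalDataset,
    n_range: Sequence[int] = tuple(range(5, 51)),
    reps: int = 1000,
    tolerance: float = 0.10,
    seed: int = 0,
    scope: str = "pooled",
    scope_key: int = 0,
    target_mean: float | None = None,
    weighted_sample_mean: bool = False,
) -> SampleSizeCurve:
    """Proportion of resampled means within ``tolerance`` of the full-data mean.

    For each sample size n, draw n site-year survival estimates without
    replacement, take their (by default unweighted) mean, and record whether
    it falls within ``tolerance * target_mean`` of the target. The target
    defaults to the pooled pup-weighted mean of ``dataset`` — the best
    estimate using all available data. Deterministic given ``seed``; sample
    sizes exceeding the record count are skipped with a warning.
    """
    records = dataset.records
    if not records:
        raise ValueError("dataset is empty")
    if target_mean is None:
        target_mean = overall_mean_survival(dataset)
    survs = np.array([r.survival for r in records])
    weights = np.array([r.n_pups for r in records], dtype=float)
    n_avail = len(records)
    usable = [n for n in n_range if n <= n_avail]
    if len(usable) < len(list(n_range)):
        warnings.warn(
            f"scope {scope!r}: only {n_avail} records; "
            f"sample sizes above that were skipped"
        )
    props = []
    band = tolerance * target_mean
    for n in usable:
        rng = _rng_for(seed, scope_key, n)
        hits = 0
        for _ in range(reps):
            idx = rng.choice(n_avail, size=n, replace=False)
            if weighted_sample_mean:
                m = np.average(survs[idx], weights=weights[idx])
            else:
                m = survs[idx].mean()
            if abs(m - target_mean) <= band:
                hits += 1
        props.append(hits / reps)
    return SampleSizeCurve(
        scope=scope,
        n_values=tuple(usable),
        proportion_within=tuple(props),
        tolerance=tolerance,
        reps=reps,
        target_mean=float(target_mean),
        seed=seed,
    )


def required_n(curve: SampleSizeCurve, threshold: float = 0.80) -> int:
    """Smallest sample size whose proportion-within reaches ``threshold``.

    Returns :data:`NOT_REACHED` (-1) if no sample size in the curve attains it.
    """
    if not curve.n_values:
        raise ValueError("empty curve")
    for n, p in zip(curve.n_values, curve.proportion_within):
        if p >= threshold:
            return n
    return NOT_REACHED
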