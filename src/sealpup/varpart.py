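"""Hierarchical partitioning of explained variance (Chevan & Sutherland).

When predictors are correlated — and "site", "sampling area" and "year" are
strongly so, since sites are nested in areas and monitored in different year
spans — the incremental R^2 a predictor contributes depends on the order in
which predictors enter the model. Hierarchical partitioning removes that
arbitrariness by averaging each predictor's incremental contribution over
every possible entry order. The average is the predictor's *independent*
contribution I; the difference between its single-predictor R^2 and I is the
*joint* contribution J attributable to shared information with the others.

Goodness of fit is the R^2 of an ordinary least-squares fit of the survival
proportion on indicator-coded categorical predictors; year is treated as
categorical (the linear trend is tested separately elsewhere).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = ["VariancePartition", "subset_r2", "hierarchical_partition", "PREDICTORS"]

PREDICTORS = ("area", "site", "year")

_FIELD = {"area": "area_id", "site": "site_id", "year": "year"}


@dataclass(frozen=True)
class VariancePartition:
    """Independent (I) and joint (J) explained-variance contributions.

    ``independent`` and ``joint`` are in R^2 units; ``percent`` expresses each
    I as a percentage of the summed independent contributions (equivalently of
    the full-model R^2, which the I's sum to exactly).
    """

    independent: dict[str, float]
    joint: dict[str, float]
    percent: dict[str, float]
    r2_full: float


def _design_matrix(dataset: SurvivalDataset, predictors: tuple[str, ...]) -> np.ndarray:
    """Intercept plus full indicator coding of the selected predictors.

    Full (one column per level) dummy coding is rank-deficient by
    construction; the minimum-norm least-squares solution makes R^2
    well-defined regardless.
    """
    n = len(dataset.records)
    cols = [np.ones(n)]
    for p in predictors:
        values = [getattr(r, _FIELD[p]) for r in dataset.records]
        dummies = pd.get_dummies(pd.Series(values, dtype="object"))
        cols.append(dummies.to_numpy(dtype=float))
    return np.column_stack(cols)


def subset_r2(
    dataset: SurvivalDataset,
    predictors: tuple[str, ...] | frozenset[str] | set[str],
    weighted: bool = False,
) -> float:
    """R^2 of survival regressed on a subset of {area, site, year}.

    The empty subset is the null model (R^2 = 0). With ``weighted`` True,
    rows are weighted by pup count (weighted least squares on sqrt-scaled
    rows); the default is unweighted.
    """
    predictors = tuple(sorted(set(predictors)))
    unknown = set(predictors) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictors {sorted(unknown)}")
    y = np.array([r.survival for r in dataset.records], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct response values")
    if not predictors:
        return 0.0
    X = _design_matrix(dataset, predictors)
    if weighted:
        w = np.sqrt(np.array([r.n_pups for r in dataset.records], dtype=float))
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    if weighted:
        w2 = np.array([r.n_pups for r in dataset.records], dtype=float)
        ybar = np.average(y, weights=w2)
        tss = float(np.sum(w2 * (y - ybar) ** 2))
    else:
        tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss
    rank = np.linalg.matrix_rank(Xw)
    if len(y) <= rank:
        warnings.warn(
            f"saturated fit ({len(y)} rows, rank {rank}); R^2 forced to 1"
        )
        return 1.0
    # numerical guard: lstsq residuals can stray a hair outside [0, 1]
    return float(min(max(r2, 0.0), 1.0))


def hierarchical_partition(
    dataset: SurvivalDataset, weighted: bool = False
) -> VariancePartition:
    """Partition explained variance in survival among area, site and year.

    For each predictor j the independent contribution is

        I_j = sum over subsets S not containing j of
              w(S) * [R^2(S + j) - R^2(S)],   w(S) = |S|!(k-|S|-1)!/k!

    which equals the average incremental R^2 of j over all k! entry orders.
    J_j = R^2({j}) - I_j. The I_j sum to the full-model R^2 exactly. Tiny
    negative I from floating point are clamped to 0 before percentages.
    """
    k = len(PREDICTORS)
    r2: dict[frozenset[str], float] = {}
    for size in range(k + 1):
        for subset in combinations(PREDICTORS, size):
            r2[frozenset(subset)] = subset_r2(dataset, subset, weighted=weighted)
    independent: dict[str, float] = {}
    joint: dict[str, float] = {}
    for j in PREDICTORS:
        others = [p for p in PREDICTORS if p != j]
        i_j = 0.0
        for size in range(k):
            w = math.factorial(size) * math.factorial(k - size - 1) / math.factorial(k)
            for subset in combinations(others, size):
                s = frozenset(subset)
                i_j += w * (r2[s | {j}] - r2[s])
        independent[j] = i_j
        joint[j] = r2[frozenset({j})] - i_j
    r2_full = r2[frozenset(PREDICTORS)]
    clamped = {j: (0.0 if -1e-12 < v < 0.0 else v) for j, v in independent.items()}
    total_i = sum(clamped.values())
    percent = {j: 100.0 * v / total_i for j, v in clamped.items()}
    return VariancePartition(
        independent=clamped, joint=joint, percent=percent, r2_full=r2_full
    )
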