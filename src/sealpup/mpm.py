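"""Seven-stage female-only grey seal matrix population models.

The life cycle has a pup stage (age 0-1), prebreeding female stages, and
breeding-age females. Only the pup-stage survival is informed by the census:
the matrix entry is S_P = S_E * S_L, the product of the measured early-stage
survival (birth to Stage IV, ~20 days) and an assumed-constant late-stage
survival from Stage IV to age 1. S_L itself is calibrated so that at the
overall mean S_E the birth-to-age-1 survival matches a published
low-density estimate of 0.48 — hence S_L = 0.48 / mean(S_E), about 0.70.
All other vital rates are fixed literature values: annual survival 0.95 for
prebreeders and breeders, fecundity 0.90 pups per breeding female, halved by
the 50:50 birth sex ratio for a female-based model.

Two structure presets cover an ambiguity in how the seven stages are split:

* ``age_structured_6plus`` (default): 1 pup stage, five prebreeder age
  classes (ages 1-5), and a single 6+ breeding class with a self-loop; only
  the 6+ class reproduces.
* ``two_breeding_stages``: 1 pup stage, four prebreeder classes, and two
  breeding classes (both reproducing, self-loop on the last).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .aggregate import weighted_mean_survival
from .data import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DemographyParams",
    "StageMatrix",
    "MatrixSet",
    "STRUCTURES",
    "N_STAGES",
    "estimate_late_survival",
    "build_mpm",
    "growth_rate",
    "stable_stage_distribution",
    "rank_sites",
    "build_matrix_sets",
]

N_STAGES = 7
STRUCTURES = ("age_structured_6plus", "two_breeding_stages")


@dataclass(frozen=True)
class DemographyParams:
    """Fixed vital rates around the census-informed pup survival.

    All probabilities are annual. ``s01_ref`` is the reference birth-to-age-1
    survival at low population density used to calibrate ``s_late``.
    """

    s_pre: float = 0.95        # prebreeder annual survival
    s_breed: float = 0.95      # breeding-female annual survival
    fecundity: float = 0.90    # pups per breeding female per year
    sex_ratio: float = 0.5     # fraction female at birth
    s01_ref: float = 0.48      # reference birth -> age 1 survival
    s_late: float = 0.70       # S_L: Stage IV -> age 1 survival

    def __post_init__(self) -> None:
        for name in ("s_pre", "s_breed", "fecundity", "sex_ratio", "s01_ref", "s_late"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def f_entry(self) -> float:
        """Female-only fecundity entry: fecundity x sex ratio."""
        return self.fecundity * self.sex_ratio


@dataclass(frozen=True)
class StageMatrix:
    """A 7x7 projection matrix plus the parameters that built it."""

    matrix: np.ndarray
    s_e: float
    label: str = ""
    structure: str = "age_structured_6plus"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"matrix must be {N_STAGES}x{N_STAGES}, got {m.shape}")
        if (m < 0).any():
            raise ValueError("matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class MatrixSet:
    """A labelled, non-empty list of matrices sharing one structure preset."""

    label: str
    matrices: tuple[StageMatrix, ...]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("matrix set is empty")
        structures = {m.structure for m in self.matrices}
        if len(structures) > 1:
            raise ValueError(f"mixed structure presets in set: {structures}")

    def __len__(self) -> int:
        return len(self.matrices)


def estimate_late_survival(s01_ref: float, s_e_overall: float) -> float:
    """Late-stage survival S_L = s01_ref / overall early-stage survival.

    Raises if the quotient exceeds 1, which would mean the measured early
    survival is below the reference birth-to-age-1 survival — an impossible
    late-stage probability.
    """
    if s_e_overall <= 0:
        raise ValueError("overall early survival must be positive")
    s_late = s01_ref / s_e_overall
    if s_late > 1.0:
        raise ValueError(
            f"s01_ref/s_e = {s_late:.4f} > 1: early survival below the "
            "reference birth-to-age-1 survival implies impossible late survival"
        )
    return s_late


def build_mpm(
    s_e: float,
    params: DemographyParams = DemographyParams(),
    structure: str = "age_structured_6plus",
    label: str = "",
) -> StageMatrix:
    """Build a 7-stage matrix with pup entry S_P = s_e * s_late.

    Stage order is pup first, then prebreeders youngest to oldest, breeding
    stage(s) last. Column j holds the per-capita contributions of stage j to
    each stage one year later.
    """
    if not (0.0 <= s_e <= 1.0):
        raise ValueError(f"s_e={s_e} outside [0, 1]")
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; options {STRUCTURES}")
    s_p = s_e * params.s_late
    A = np.zeros((N_STAGES, N_STAGES))
    if structure == "age_structured_6plus":
        A[1, 0] = s_p
        for j in range(1, 6):            # ages 1-5 advance one class
            A[j + 1, j] = params.s_pre
        A[6, 6] = params.s_breed         # 6+ self-loop
        A[0, 6] = params.f_entry
    else:  # two_breeding_stages
        A[1, 0] = s_p
        for j in range(1, 5):            # four prebreeder classes advance
            A[j + 1, j] = params.s_pre
        A[6, 5] = params.s_breed         # first breeding stage survives on
        A[6, 6] = params.s_breed         # final breeding stage self-loop
        A[0, 5] = params.f_entry
        A[0, 6] = params.f_entry
    survival_part = A.copy()
    survival_part[0, :] = 0.0
    if (survival_part > 1.0).any() or A[0].max() > params.fecundity:
        raise ValueError("matrix entry outside its admissible range")
    return StageMatrix(matrix=A, s_e=float(s_e), label=label, structure=structure)


def growth_rate(m: StageMatrix | np.ndarray) -> float:
    """Asymptotic population growth rate: the dominant eigenvalue.

    For the matrices built here the dominant eigenvalue is real and positive
    (the life-cycle graph is primitive). lambda > 1 means asymptotic growth.
    """
    A = m.matrix if isinstance(m, StageMatrix) else np.asarray(m, dtype=float)
    eigvals = np.linalg.eigvals(A)
    lam = eigvals[np.argmax(np.abs(eigvals))]
    if abs(lam.imag) > 1e-9 * max(abs(lam), 1.0):
        raise ValueError(f"dominant eigenvalue not real: {lam}")
    return float(lam.real)


def stable_stage_distribution(m: StageMatrix | np.ndarray) -> np.ndarray:
    """Dominant right eigenvector, normalised to sum to 1."""
    A = m.matrix if isinstance(m, StageMatrix) else np.asarray(m, dtype=float)
    eigvals, eigvecs = np.linalg.eig(A)
    v = eigvecs[:, np.argmax(np.abs(eigvals))].real
    if v.sum() < 0:
        v = -v
    if (v < -1e-9 * abs(v).max()).any():
        raise ValueError("dominant eigenvector not non-negative")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def site_mean_survivals(
    dataset: SurvivalDataset, weight_field: str = "n_pups"
) -> dict[str, float]:
    """Across-year pup-weighted mean survival per site."""
    out = {}
    for site in dataset.sites:
        recs = [r for r in dataset.records if r.site_id == site]
        out[site] = weighted_mean_survival(recs, weight_field)
    return out


def rank_sites(
    dataset: SurvivalDataset, k: int = 10, weight_field: str = "n_pups"
) -> tuple[list[str], list[str]]:
    """The k consistently worst- and best-performing sites by mean survival.

    Sites are ordered by their across-year pup-weighted mean survival; ties
    are broken by site label (logged when they occur at a cut boundary).
    """
    means = site_mean_survivals(dataset, weight_field)
    if len(means) < 2 * k:
        raise ValueError(f"need at least {2 * k} sites, have {len(means)}")
    ordered = sorted(means, key=lambda s: (means[s], s))
    worst, best = ordered[:k], ordered[-k:]
    for boundary, inside in ((ordered[k - 1], ordered[k]), (ordered[-k], ordered[-k - 1])):
        if means[boundary] == means[inside]:
            logger.info("rank_sites: tie at cut boundary broken by site label")
    return worst, best


def build_matrix_sets(
    dataset: SurvivalDataset,
    params: DemographyParams = DemographyParams(),
    structure: str = "age_structured_6plus",
    k: int = 10,
    weight_field: str = "n_pups",
) -> dict[str, MatrixSet]:
    """Assemble the matrix sets used to probe data-aggregation choices.

    * ``per_site`` — one matrix per site from its across-year weighted mean;
    * ``per_area`` — one per sampling area;
    * ``worst_best_pooled`` — two matrices, from the pooled weighted mean of
      the k worst- and k best-performing sites' records;
    * ``worst_best_per_site`` — one per site in the worst-k and best-k (2k);
    * ``worst_site_years`` / ``best_site_years`` — a matrix for every
      site-year of the worst-k / best-k sites, preserving temporal variation
      for stochastic projection.
    """
    if not dataset.records:
        raise ValueError("dataset is empty")

    def mk(s_e: float, label: str) -> StageMatrix:
        return build_mpm(s_e, params, structure, label)

    site_means = site_mean_survivals(dataset, weight_field)
    per_site = tuple(mk(site_means[s], s) for s in sorted(site_means))

    per_area = tuple(
        mk(weighted_mean_survival(dataset.for_area(a).records, weight_field), a)
        for a in dataset.areas
    )

    worst, best = rank_sites(dataset, k, weight_field)
    pooled = []
    for label, group in (("worst", worst), ("best", best)):
        recs = [r for r in dataset.records if r.site_id in group]
        pooled.append(mk(weighted_mean_survival(recs, weight_field), label))

    per_extreme = tuple(mk(site_means[s], s) for s in sorted(worst) + sorted(best))

    def site_year_set(group: list[str], label: str) -> MatrixSet:
        mats = tuple(
            mk(r.survival, f"{r.site_id}:{r.year}")
            for r in sorted(
                (r for r in dataset.records if r.site_id in group),
                key=lambda r: (r.site_id, r.year),
            )
        )
        return MatrixSet(label=label, matrices=mats)

    return {
        "per_site": MatrixSet("per_site", per_site),
        "per_area": MatrixSet("per_area", per_area),
        "worst_best_pooled": MatrixSet("worst_best_pooled", tuple(pooled)),
        "worst_best_per_site": MatrixSet("worst_best_per_site", per_extreme),
        "worst_site_years": site_year_set(worst, "worst_site_years"),
        "best_site_years": site_year_set(best, "best_site_years"),
    }
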