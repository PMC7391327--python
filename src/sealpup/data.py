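"""Census record types, table I/O and count-correction rules.

The raw unit of observation is one breeding site in one season: the number
of pups observed there and the number judged (by repeated surveys) to have
survived to developmental Stage IV, the moulting "barrel" stage reached
around 16-20 days of age, after which a pup is independent of its mother.
Some survey protocols apply a double-counting adjustment that yields
non-integer counts and can occasionally estimate more survivors than pups;
:func:`apply_count_correction` implements the cleaning rules for both
artefacts.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SiteYearRecord",
    "SurvivalDataset",
    "SchemaError",
    "NestingError",
    "UndefinedSurvivalError",
    "apply_count_correction",
    "read_census_table",
    "write_census_table",
    "subset_years_all_areas",
]

#: default header names for census tables
DEFAULT_COLUMNS = {
    "area": "area",
    "site": "site",
    "year": "year",
    "pups": "pups",
    "survivors": "survivors",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class NestingError(ValueError):
    """A site appears under more than one sampling area."""


class UndefinedSurvivalError(ValueError):
    """Corrected pup count is zero, so the survival proportion is undefined."""


def _round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Centralised so the survey-correction rounding rule lives in one place.
    Only non-negative inputs occur in practice but the rule is symmetric.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def apply_count_correction(
    raw_pups: float, raw_survivors: float
) -> tuple[int, int, float]:
    """Clean one site-year count pair into integer counts and a survival.

    Both counts are rounded to the nearest integer (halves away from zero).
    If the rounded survivor count exceeds the rounded pup count — an artefact
    of the double-count adjustment used on cliff-top surveys — the survivor
    estimate is taken as correct: survival is capped at 1 and the pup count
    is raised to match.

    Parameters
    ----------
    raw_pups, raw_survivors
        Non-negative, possibly non-integer field estimates.

    Returns
    -------
    (n_pups, n_survivors, survival)

    Raises
    ------
    UndefinedSurvivalError
        If the rounded pup count is zero; callers should drop the record.
    """
    if raw_pups < 0 or raw_survivors < 0:
        raise ValueError("counts must be non-negative")
    n_pups = _round_half_away(raw_pups)
    n_survivors = _round_half_away(raw_survivors)
    if n_pups == 0:
        raise UndefinedSurvivalError(
            f"rounded pup count is 0 (raw {raw_pups!r}); survival undefined"
        )
    if n_survivors > n_pups:
        # survivor estimate treated as correct; probability capped at 1
        n_survivors = n_pups
        survival = 1.0
    else:
        survival = n_survivors / n_pups
    return n_pups, n_survivors, survival


@dataclass(frozen=True)
class SiteYearRecord:
    """One site-in-one-year census observation.

    ``raw_pups``/``raw_survivors`` are the pre-correction field estimates;
    ``n_pups``/``n_survivors``/``survival`` are post-correction. The survival
    proportion is the early-stage (birth to Stage IV) pup survival S_E.
    """

    area_id: str
    site_id: str
    year: int
    raw_pups: float
    raw_survivors: float
    n_pups: int
    n_survivors: int
    survival: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_survivors <= self.n_pups):
            raise ValueError(
                f"{self.site_id}/{self.year}: need 0 <= survivors <= pups, "
                f"got {self.n_survivors}/{self.n_pups}"
            )
        if not (0.0 <= self.survival <= 1.0):
            raise ValueError(f"survival {self.survival} outside [0, 1]")

    @classmethod
    def from_raw(
        cls,
        area_id: str,
        site_id: str,
        year: int,
        raw_pups: float,
        raw_survivors: float,
        correct: bool = True,
    ) -> "SiteYearRecord":
        """Build a record, applying the count correction unless ``correct`` is
        False (pre-cleaned integer data)."""
        if correct:
            n_pups, n_survivors, survival = apply_count_correction(
                raw_pups, raw_survivors
            )
        else:
            n_pups, n_survivors = int(raw_pups), int(raw_survivors)
            if n_pups == 0:
                raise UndefinedSurvivalError(
                    f"{site_id}/{year}: zero pups, survival undefined"
                )
            survival = min(n_survivors / n_pups, 1.0)
        return cls(
            area_id=str(area_id),
            site_id=str(site_id),
            year=int(year),
            raw_pups=float(raw_pups),
            raw_survivors=float(raw_survivors),
            n_pups=n_pups,
            n_survivors=n_survivors,
            survival=survival,
        )


@dataclass
class SurvivalDataset:
    """A collection of site-year records with the site-in-area nesting.

    Invariants checked on construction: (site, year) pairs are unique, every
    record's site appears in ``nesting``, and each site maps to exactly one
    area.
    """

    records: list[SiteYearRecord]
    nesting: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nesting:
            self.nesting = {}
            for r in self.records:
                prev = self.nesting.setdefault(r.site_id, r.area_id)
                if prev != r.area_id:
                    raise NestingError(
                        f"site {r.site_id!r} appears under areas "
                        f"{prev!r} and {r.area_id!r}"
                    )
        seen: set[tuple[str, int]] = set()
        for r in self.records:
            key = (r.site_id, r.year)
            if key in seen:
                raise ValueError(f"duplicate (site, year) pair {key}")
            seen.add(key)
            if r.site_id not in self.nesting:
                raise NestingError(f"site {r.site_id!r} missing from nesting")
            if self.nesting[r.site_id] != r.area_id:
                raise NestingError(
                    f"site {r.site_id!r} recorded in area {r.area_id!r} but "
                    f"nested in {self.nesting[r.site_id]!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def areas(self) -> list[str]:
        return sorted({r.area_id for r in self.records})

    @property
    def sites(self) -> list[str]:
        return sorted({r.site_id for r in self.records})

    @property
    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per record (post-correction fields included)."""
        return pd.DataFrame(
            {
                "area": [r.area_id for r in self.records],
                "site": [r.site_id for r in self.records],
                "year": [r.year for r in self.records],
                "pups": [r.raw_pups for r in self.records],
                "survivors": [r.raw_survivors for r in self.records],
                "n_pups": [r.n_pups for r in self.records],
                "n_survivors": [r.n_survivors for r in self.records],
                "survival": [r.survival for r in self.records],
            }
        )

    def filter(self, predicate) -> "SurvivalDataset":
        """Dataset of the records satisfying ``predicate`` (nesting retained)."""
        kept = [r for r in self.records if predicate(r)]
        return SurvivalDataset(records=kept, nesting=dict(self.nesting))

    def drop_site(self, site_id: str) -> "SurvivalDataset":
        return self.filter(lambda r: r.site_id != site_id)

    def for_area(self, area_id: str) -> "SurvivalDataset":
        return self.filter(lambda r: r.area_id == area_id)

    def for_site(self, site_id: str) -> "SurvivalDataset":
        return self.filter(lambda r: r.site_id == site_id)


def read_census_table(
    path: str | Path,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
    correct: bool = True,
) -> SurvivalDataset:
    """Read a delimited census table into a :class:`SurvivalDataset`.

    Expected header (configurable via ``columns``):
    ``area,site,year,pups,survivors``. The count correction is applied to
    every row unless ``correct`` is False; rows whose corrected pup count is
    zero are excluded and the exclusion count logged.

    Raises
    ------
    SchemaError
        If a required column is missing.
    NestingError
        If a site appears under two areas.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=delimiter)
    missing = [name for name in cols.values() if name not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records: list[SiteYearRecord] = []
    n_excluded = 0
    for _, row in df.iterrows():
        try:
            records.append(
                SiteYearRecord.from_raw(
                    area_id=row[cols["area"]],
                    site_id=row[cols["site"]],
                    year=int(row[cols["year"]]),
                    raw_pups=float(row[cols["pups"]]),
                    raw_survivors=float(row[cols["survivors"]]),
                    correct=correct,
                )
            )
        except UndefinedSurvivalError:
            n_excluded += 1
    if n_excluded:
        logger.info(
            "read_census_table: excluded %d row(s) with zero corrected pups",
            n_excluded,
        )
    return SurvivalDataset(records=records)


def write_census_table(
    dataset: SurvivalDataset, path: str | Path, delimiter: str = ","
) -> None:
    """Write the dataset as a delimited table (raw and corrected columns)."""
    dataset.to_frame().to_csv(path, sep=delimiter, index=False)


def subset_years_all_areas(dataset: SurvivalDataset) -> SurvivalDataset:
    """Keep only years in which every sampling area has at least one record.

    Unbalanced monitoring histories mean the areas overlap for only part of
    the study period; area-comparable statistics are computed on this subset.
    Idempotent; warns and returns an empty dataset if no year qualifies.
    """
    if not dataset.records:
        raise ValueError("dataset is empty")
    all_areas = set(dataset.areas)
    years_by_area: dict[str, set[int]] = {a: set() for a in all_areas}
    for r in dataset.records:
        years_by_area[r.area_id].add(r.year)
    common = set.intersection(*years_by_area.values())
    if not common:
        warnings.warn("no year is represented in every area; result is empty")
    return dataset.filter(lambda r: r.year in common)
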