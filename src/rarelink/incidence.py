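"""Birth-cohort minimal incidence from de-duplicated patients.

Incidence is computed per birth year as distinct ascertained patients over
live births of that year, scaled to a convenient base (default 10,000).
Because any patient missed by all three reporting sources is invisible,
the result is a *minimal* incidence — a lower bound on the true rate.
Advisory flags mark birth years likely to be under-ascertained: the most
recent cohorts (patients not yet diagnosed or reported) and years where a
single source dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dedup_merge import DistinctPatient
from .records_io import DiseaseGroup, SourceType, Subtype

__all__ = [
    "NatalityTable",
    "compute_incidence",
    "peak_incidence",
    "underascertainment_note",
]


@dataclass(frozen=True)
class NatalityTable:
    """Live births per calendar year — the incidence denominator."""

    births: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.births:
            raise ValueError("natality table is empty")
        for year, n in self.births.items():
            if n <= 0:
                raise ValueError(f"non-positive live births for {year}")
        years = sorted(self.births)
        gaps = [y for y in range(years[0], years[-1] + 1) if y not in self.births]
        if gaps:
            raise ValueError(f"natality table has missing years inside its window: {gaps}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NatalityTable":
        df = pd.read_csv(path)
        if not {"year", "live_births"} <= set(df.columns):
            raise ValueError("natality CSV needs columns year, live_births")
        return cls(dict(zip(df["year"].astype(int), df["live_births"].astype(int))))

    def __getitem__(self, year: int) -> int:
        return self.births[year]

    def years(self) -> list[int]:
        return sorted(self.births)


#: Disease labels and their patient selectors. "DMD" deliberately counts
#: only patients *resolved* to the Duchenne subtype — excluding Becker and
#: unclassified dystrophinopathies — because a DMD-specific incidence over
#: the whole dystrophinopathy group would be inflated.
_SELECTORS = {
    "DMD": lambda p: p.final_subtype is Subtype.DMD,
    "SMA": lambda p: p.disease_group is DiseaseGroup.SMA,
}


def _round2(numerator: int, denominator: int, per: int) -> float:
    val = (Decimal(numerator) * per / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(val)


def compute_incidence(
    patients: Sequence[DistinctPatient],
    natality: NatalityTable,
    per: int = 10_000,
    diseases: Iterable[str] = ("DMD", "SMA"),
) -> pd.DataFrame:
    """Per-year minimal incidence, one row per (disease, birth year).

    Columns: disease, birth_year, n_patients, live_births, incidence
    (per ``per`` live births, 2 decimals, half-up). Every patient birth
    year must be covered by the natality table.
    """
    for d in diseases:
        if d not in _SELECTORS:
            raise ValueError(f"unknown disease label {d!r}; known: {sorted(_SELECTORS)}")
    covered = set(natality.years())
    uncovered = {p.birth_year for p in patients} - covered
    if uncovered:
        raise ValueError(f"birth years without natality data: {sorted(uncovered)}")
    rows = []
    for d in diseases:
        sel = _SELECTORS[d]
        by_year: dict[int, int] = {y: 0 for y in natality.years()}
        for p in patients:
            if sel(p):
                by_year[p.birth_year] += 1
        for year in natality.years():
            births = natality[year]
            rows.append(
                {
                    "disease": d,
                    "birth_year": year,
                    "n_patients": by_year[year],
                    "live_births": births,
                    "incidence": _round2(by_year[year], births, per),
                }
            )
    return pd.DataFrame(rows)


def peak_incidence(table: pd.DataFrame, disease: str) -> tuple[int, float]:
    """The birth year with the highest incidence (ties -> earliest year)."""
    sub = table[table["disease"] == disease]
    if sub.empty:
        raise ValueError(f"no rows for disease {disease!r}")
    best = sub.sort_values(["incidence", "birth_year"], ascending=[False, True]).iloc[0]
    return int(best["birth_year"]), float(best["incidence"])


def underascertainment_note(
    patients: Sequence[DistinctPatient],
    collection_end: int = 2018,
    recent_window: int = 2,
    dominance_threshold: float = 0.8,
) -> pd.DataFrame:
    """Advisory per-year flags for likely under-ascertainment.

    A birth year is flagged when it lies within ``recent_window`` years of
    the end of data collection (patients may not yet have reached diagnosis
    or reporting), or when more than ``dominance_threshold`` of its
    patients were reported by a single source alone (the other sources are
    effectively blind to that cohort).
    """
    years = sorted({p.birth_year for p in patients})
    rows = []
    for year in years:
        cohort = [p for p in patients if p.birth_year == year]
        reasons = []
        if collection_end - year < recent_window:
            reasons.append("recent birth cohort")
        for source in SourceType:
            only = sum(1 for p in cohort if p.source_types == frozenset({source}))
            if cohort and only / len(cohort) > dominance_threshold:
                reasons.append(f"{source.value} contributes >{dominance_threshold:.0%} alone")
        rows.append(
            {
                "birth_year": year,
                "n_patients": len(cohort),
                "flagged": bool(reasons),
                "reasons": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["birth_year", "n_patients", "flagged", "reasons"])
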