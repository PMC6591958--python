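"""Aggregate outputs under small-cell suppression.

Data extracts from a rare-disease linkage database must not expose small
groups: any released cell counting between 1 and k-1 individuals (k = 5 by
default) is replaced by a "<k" token. Because a suppressed cell could be
recovered from a published row total, complementary suppression is applied:
whenever the suppressed cells of a row are uniquely solvable from the
margin, the next-smallest positive cell is suppressed as well (and if
nothing is left to suppress, the margin itself is withheld). Zero cells are
released — a zero describes no individual.

Percentages are computed on the unsuppressed counts and rounded half-up to
one decimal; a suppressed cell releases neither its count nor its percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dedup_merge import ClassificationBasis, DistinctPatient, OverlapCell, overlap_cell
from .records_io import DiseaseGroup, DiagnosisAge, SourceType, SPECIFIC_SUBTYPES, Subtype

__all__ = [
    "AggregateTable",
    "RegistryStats",
    "GeneticOnlyReport",
    "percentage",
    "overlap_summary",
    "subtype_distribution",
    "genetic_only_diagnosis_age",
    "registry_participation",
    "regional_distribution",
    "suppress",
    "DEFAULT_K",
]

DEFAULT_K = 5
SUPPRESSED = object()  # sentinel in released frames is the "<k" string


def _round_half_up(numerator: int, denominator: int, scale: int, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(numerator) * scale / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(val)


def percentage(count: int, denominator: int) -> float:
    """Percent of a stated denominator, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count <= denominator):
        raise ValueError("count must lie in [0, denominator]")
    return _round_half_up(count, denominator, 100, 1)


@dataclass
class AggregateTable:
    """Labeled counts with percentages of a stated denominator.

    ``counts`` maps row label -> non-negative integer. ``denominator`` is
    the population the percentages refer to (it may exceed the sum of rows
    for non-partition tables). ``suppressed`` lists labels whose cells are
    withheld on release; ``margin_published`` records whether the row total
    may be printed alongside.
    """

    counts: dict[str, int]
    denominator: Optional[int]
    k: int = DEFAULT_K
    suppressed: frozenset[str] = frozenset()
    margin_published: bool = True
    extra: dict[str, dict[str, float]] = field(default_factory=dict)

    def percent(self, label: str) -> Optional[float]:
        if self.denominator in (None, 0):
            return None
        return percentage(self.counts[label], self.denominator)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def released(self) -> pd.DataFrame:
        """The disclosure-safe view: suppressed cells show ``"<k"`` and no
        percentage; the margin row appears only if publishable."""
        token = f"<{self.k}"
        rows = []
        for label, n in self.counts.items():
            hidden = label in self.suppressed
            rows.append(
                {
                    "label": label,
                    "count": token if hidden else n,
                    "percent": None if (hidden or self.denominator in (None, 0)) else self.percent(label),
                }
            )
        if self.margin_published:
            rows.append({"label": "TOTAL", "count": self.total, "percent": None})
        return pd.DataFrame(rows, columns=["label", "count", "percent"])


def suppress(table: AggregateTable, k: int = DEFAULT_K) -> AggregateTable:
    """Apply k-threshold suppression with complementary protection.

    Primary rule: cells with 1 <= count < k are suppressed; zeros are
    released. If the row total is published, the suppressed cells must not
    be solvable from it: whenever the remaining hidden mass admits only one
    integer solution (a single hidden cell, or hidden mass equal to the
    number of hidden cells, forcing all ones), the next-smallest positive
    visible cell is suppressed too; if no such cell remains, the margin is
    withheld instead. Increasing k never reveals a previously hidden cell.
    """
    if k < 2:
        raise ValueError("suppression threshold k must be >= 2")
    hidden = {label for label, n in table.counts.items() if 1 <= n < k}
    margin_published = table.margin_published
    if margin_published:
        while hidden:
            hidden_mass = sum(table.counts[l] for l in hidden)
            if len(hidden) != 1 and hidden_mass != len(hidden):
                break  # multiple integer solutions exist for every hidden cell
            candidates = sorted(
                (n, l) for l, n in table.counts.items() if l not in hidden and n >= 1
            )
            if not candidates:
                margin_published = False
                break
            hidden.add(candidates[0][1])
    return replace(
        table,
        k=k,
        suppressed=frozenset(hidden) | table.suppressed,
        margin_published=margin_published,
    )


_CELL_LABELS = {
    OverlapCell.CENTER_ONLY: "CENTER_ONLY",
    OverlapCell.GENETIC_ONLY: "GENETIC_ONLY",
    OverlapCell.REGISTRY_ONLY: "REGISTRY_ONLY",
    OverlapCell.CENTER_GENETIC: "CENTER+GENETIC",
    OverlapCell.CENTER_REGISTRY: "CENTER+REGISTRY",
    OverlapCell.GENETIC_REGISTRY: "GENETIC+REGISTRY",
    OverlapCell.ALL_THREE: "ALL_THREE",
}


def _in_scope(patients: Iterable[DistinctPatient], disease_group: Optional[DiseaseGroup]):
    return [p for p in patients if disease_group is None or p.disease_group is disease_group]


def overlap_summary(
    patients: Sequence[DistinctPatient],
    disease_group: Optional[DiseaseGroup] = None,
    detail: str = "n_sources",
    k: int = DEFAULT_K,
) -> AggregateTable:
    """Source-overlap distribution of distinct patients.

    ``detail="n_sources"`` counts patients found in 1, 2 or 3 sources;
    ``detail="cells"`` resolves the 7 source-combination cells. Scope is one
    disease group or, with ``disease_group=None``, both combined. The
    denominator is the number of distinct patients in scope.
    """
    scope = _in_scope(patients, disease_group)
    if detail == "n_sources":
        counts = {"1_SOURCE": 0, "2_SOURCES": 0, "3_SOURCES": 0}
        for p in scope:
            counts[f"{p.n_sources}_SOURCE{'S' if p.n_sources > 1 else ''}"] += 1
    elif detail == "cells":
        counts = {label: 0 for label in _CELL_LABELS.values()}
        for p in scope:
            counts[_CELL_LABELS[overlap_cell(p)]] += 1
    else:
        raise ValueError(f"unknown detail {detail!r}")
    return AggregateTable(counts, denominator=len(scope) or None, k=k)


def subtype_distribution(
    patients: Sequence[DistinctPatient],
    disease_group: DiseaseGroup,
    restrict_to_sources: Optional[set[SourceType]] = None,
    k: int = DEFAULT_K,
) -> AggregateTable:
    """Distribution of resolved subtypes within one disease group.

    ``restrict_to_sources`` keeps only patients reported by at least one of
    the named source types — e.g. restricting SMA to center- or
    registry-reported patients, the sub-population whose clinical type is
    actually collected.
    """
    if not isinstance(disease_group, DiseaseGroup):
        raise ValueError(f"unknown disease group {disease_group!r}")
    scope = [p for p in patients if p.disease_group is disease_group]
    if restrict_to_sources is not None:
        scope = [p for p in scope if p.source_types & restrict_to_sources]
    order = sorted(SPECIFIC_SUBTYPES[disease_group], key=lambda s: s.value) + [Subtype.UNSPECIFIED]
    counts = {s.value: 0 for s in order}
    for p in scope:
        counts[p.final_subtype.value] += 1
    return AggregateTable(counts, denominator=len(scope) or None, k=k)


@dataclass
class GeneticOnlyReport:
    """Patients seen by genetic institutes alone, and when they were
    diagnosed. ``share`` counts them against the whole cohort in scope;
    ``ages`` distributes them over diagnosis-age categories."""

    share: AggregateTable
    ages: AggregateTable


def genetic_only_diagnosis_age(
    patients: Sequence[DistinctPatient],
    disease_group: DiseaseGroup = DiseaseGroup.SMA,
    k: int = DEFAULT_K,
) -> GeneticOnlyReport:
    scope = [p for p in patients if p.disease_group is disease_group]
    genetic_only = [
        p for p in scope if p.source_types == frozenset({SourceType.GENETIC_INSTITUTE})
    ]
    share = AggregateTable(
        {"GENETIC_ONLY": len(genetic_only)}, denominator=len(scope) or None, k=k,
        margin_published=False,
    )
    age_counts = {cat.value: 0 for cat in DiagnosisAge}
    age_counts["UNKNOWN"] = 0
    for p in genetic_only:
        key = p.age_at_genetic_diagnosis if p.age_at_genetic_diagnosis is not None else "UNKNOWN"
        age_counts[key] += 1
    ages = AggregateTable(age_counts, denominator=len(genetic_only) or None, k=k)
    return GeneticOnlyReport(share, ages)


@dataclass(frozen=True)
class RegistryStats:
    """Registry participation within one disease label."""

    n_patients: int
    n_registry: int
    n_registry_in_center_care: int

    @property
    def participation_pct(self) -> Optional[float]:
        return percentage(self.n_registry, self.n_patients) if self.n_patients else None

    @property
    def care_pct(self) -> Optional[float]:
        return percentage(self.n_registry_in_center_care, self.n_registry) if self.n_registry else None


def registry_participation(patients: Sequence[DistinctPatient]) -> dict[str, RegistryStats]:
    """Per-disease registry participation and specialist-care coverage.

    Keys: ``"DMD"`` (dystrophinopathy patients resolved to the Duchenne
    subtype — the registry is disease-specific) and ``"SMA"`` (the whole
    SMA group). For each: how many distinct patients appear in the registry
    at all, and how many of those report being regularly under specialist
    care.
    """
    out: dict[str, RegistryStats] = {}
    selections = {
        "DMD": [p for p in patients if p.final_subtype is Subtype.DMD],
        "SMA": [p for p in patients if p.disease_group is DiseaseGroup.SMA],
    }
    for label, scope in selections.items():
        registry = [p for p in scope if SourceType.PATIENT_REGISTRY in p.source_types]
        cared = [p for p in registry if p.in_center_care is True]
        out[label] = RegistryStats(len(scope), len(registry), len(cared))
    return out


def regional_distribution(
    patients: Sequence[DistinctPatient],
    population_by_region: Mapping[int, int],
    k: int = DEFAULT_K,
) -> AggregateTable:
    """Patients per leading postal digit and per 100,000 inhabitants.

    Patients with unknown region are pooled in an ``UNKNOWN`` row that is
    excluded from rates. Rates (2 decimals, half-up) are attached in
    ``extra["per_100k"]``.
    """
    missing_digits = set(range(10)) - set(population_by_region)
    if missing_digits:
        raise ValueError(f"population table must cover digits 0-9; missing {sorted(missing_digits)}")
    counts = {str(d): 0 for d in range(10)}
    counts["UNKNOWN"] = 0
    for p in patients:
        counts[str(p.postal_region) if p.postal_region is not None else "UNKNOWN"] += 1
    rates: dict[str, float] = {}
    for d in range(10):
        pop = population_by_region[d]
        if counts[str(d)] and pop <= 0:
            raise ValueError(f"zero population for region {d} with patients present")
        rates[str(d)] = _round_half_up(counts[str(d)], pop, 100_000, 2) if pop > 0 else 0.0
    table = AggregateTable(counts, denominator=len(patients) or None, k=k)
    table.extra["per_100k"] = rates
    return table
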