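"""Collapse entries sharing a pseudonym into distinct patients.

The de-duplication unit is the pseudonym: every entry carrying the same
linkage token is, by construction of the hashing layer, a report on the
same individual (or on two individuals who share a birth date and initials
— an intrinsic, quantifiable limitation handled in the synthetic-cohort
module, not here).

Diagnosis conflicts are resolved by precedence:

1. The clinical specialist (neuromuscular-center) diagnosis wins over
   genetic-institute and registry reports.
2. Two centers (or one center contradicting itself) disagreeing on the
   specific subtype leave the patient unclassified.
3. Without any center report, a single non-center specific subtype, or
   several concordant ones, is accepted; conflicting non-center reports
   leave the patient unclassified. No rule ever invents a subtype.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .records_io import (
    DiseaseGroup,
    EntryTable,
    SourceEntry,
    SourceType,
    SPECIFIC_SUBTYPES,
    Subtype,
)

__all__ = [
    "ClassificationBasis",
    "DistinctPatient",
    "OverlapCell",
    "IntegrityError",
    "group_by_pseudonym",
    "resolve_diagnosis",
    "build_distinct_patients",
    "overlap_cell",
]


class IntegrityError(ValueError):
    """Entries under one pseudonym are mutually impossible (e.g. different
    birth years, which cannot happen if all sites hash the same dialect)."""


class ClassificationBasis(str, Enum):
    CENTER = "CENTER"
    SINGLE_NONCENTER = "SINGLE_NONCENTER"
    CONCORDANT_NONCENTER = "CONCORDANT_NONCENTER"
    UNRESOLVED = "UNRESOLVED"


class OverlapCell(Enum):
    """The 7 non-empty source combinations a patient can be reported by."""

    CENTER_ONLY = frozenset({SourceType.NEUROMUSCULAR_CENTER})
    GENETIC_ONLY = frozenset({SourceType.GENETIC_INSTITUTE})
    REGISTRY_ONLY = frozenset({SourceType.PATIENT_REGISTRY})
    CENTER_GENETIC = frozenset({SourceType.NEUROMUSCULAR_CENTER, SourceType.GENETIC_INSTITUTE})
    CENTER_REGISTRY = frozenset({SourceType.NEUROMUSCULAR_CENTER, SourceType.PATIENT_REGISTRY})
    GENETIC_REGISTRY = frozenset({SourceType.GENETIC_INSTITUTE, SourceType.PATIENT_REGISTRY})
    ALL_THREE = frozenset(SourceType)

    @classmethod
    def from_sources(cls, sources: frozenset[SourceType] | set[SourceType]) -> "OverlapCell":
        fs = frozenset(sources)
        for cell in cls:
            if cell.value == fs:
                return cell
        raise ValueError(f"not a non-empty source subset: {sources!r}")


class DistinctPatient(BaseModel):
    """The merged record for one pseudonym."""

    model_config = ConfigDict(frozen=True)

    pseudonym: str
    source_types: frozenset[SourceType]
    disease_group: DiseaseGroup
    final_subtype: Subtype
    classification_basis: ClassificationBasis
    birth_year: int
    postal_region: Optional[int] = None
    age_at_genetic_diagnosis: Optional[str] = None
    in_center_care: Optional[bool] = None
    n_entries: int = 1

    @property
    def n_sources(self) -> int:
        return len(self.source_types)

    @model_validator(mode="after")
    def _consistent(self) -> "DistinctPatient":
        if not self.source_types:
            raise ValueError("source_types must be non-empty")
        if (
            self.final_subtype is not Subtype.UNSPECIFIED
            and self.final_subtype not in SPECIFIC_SUBTYPES[self.disease_group]
        ):
            raise ValueError("final_subtype inconsistent with disease_group")
        if self.classification_basis is ClassificationBasis.UNRESOLVED and self.final_subtype is not Subtype.UNSPECIFIED:
            raise ValueError("unresolved patients carry no subtype")
        return self


def group_by_pseudonym(table: EntryTable | Iterable[SourceEntry]) -> dict[str, list[SourceEntry]]:
    """Partition entries by pseudonym.

    Group sizes sum to the entry count; the number of groups is the number
    of distinct pseudonyms. Entries under one pseudonym reporting different
    birth years signal a hashing-dialect mismatch between sites and raise
    :class:`IntegrityError` (the hash input includes the full birth date,
    so a genuine link cannot disagree on birth year).
    """
    groups: dict[str, list[SourceEntry]] = {}
    for entry in table:
        groups.setdefault(entry.pseudonym, []).append(entry)
    for pseud, group in groups.items():
        years = {e.birth_year for e in group}
        if len(years) > 1:
            raise IntegrityError(
                f"pseudonym {pseud!r} carries conflicting birth years {sorted(years)}"
            )
    return groups


def resolve_diagnosis(group: list[SourceEntry]) -> tuple[Subtype, ClassificationBasis]:
    """Resolve the final subtype for all entries of one patient.

    See the module docstring for the precedence rules. All entries must
    share a disease group (a pseudonym reported under both disease groups
    is an integrity violation).
    """
    if not group:
        raise ValueError("cannot resolve an empty entry group")
    diseases = {e.disease_group for e in group}
    if len(diseases) > 1:
        raise IntegrityError(
            f"pseudonym {group[0].pseudonym!r} reported under multiple disease groups"
        )

    center = [e for e in group if e.source_type is SourceType.NEUROMUSCULAR_CENTER]
    center_specific = {e.subtype for e in center if e.subtype is not Subtype.UNSPECIFIED}
    if len(center_specific) > 1:
        # two centers disagree (or one center contradicts itself): the
        # patient is not allocated to a subgroup
        return Subtype.UNSPECIFIED, ClassificationBasis.UNRESOLVED
    if len(center_specific) == 1:
        return next(iter(center_specific)), ClassificationBasis.CENTER

    noncenter = [e for e in group if e.source_type is not SourceType.NEUROMUSCULAR_CENTER]
    # a "source" is a distinct reporting site, not a row
    specific_by_source: dict[tuple[SourceType, str], set[Subtype]] = {}
    for e in noncenter:
        if e.subtype is not Subtype.UNSPECIFIED:
            specific_by_source.setdefault((e.source_type, e.source_id), set()).add(e.subtype)
    specific = set().union(*specific_by_source.values()) if specific_by_source else set()

    if len(specific) > 1:
        return Subtype.UNSPECIFIED, ClassificationBasis.UNRESOLVED
    if len(specific) == 1:
        basis = (
            ClassificationBasis.SINGLE_NONCENTER
            if len(specific_by_source) == 1
            else ClassificationBasis.CONCORDANT_NONCENTER
        )
        return next(iter(specific)), basis

    # nothing specific anywhere
    if center:
        return Subtype.UNSPECIFIED, ClassificationBasis.CENTER
    distinct_sources = {(e.source_type, e.source_id) for e in noncenter}
    basis = (
        ClassificationBasis.SINGLE_NONCENTER
        if len(distinct_sources) == 1
        else ClassificationBasis.CONCORDANT_NONCENTER
    )
    return Subtype.UNSPECIFIED, basis


def _modal(values: list) -> Optional[object]:
    """Most frequent non-missing value; ties -> missing (never guess)."""
    present = [v for v in values if v is not None]
    if not present:
        return None
    counts = Counter(present).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def build_distinct_patients(table: EntryTable | Iterable[SourceEntry]) -> list[DistinctPatient]:
    """De-duplicate an entry table into one record per pseudonym.

    Attribute merge: birth year is identical within a group by construction;
    postal region, diagnosis-age category and in-center-care flag are taken
    as the modal value over the entries of the (unique) source type that
    collects them, with ties resolved to missing. Output is sorted by
    pseudonym so results do not depend on entry order.
    """
    groups = group_by_pseudonym(table)
    patients: list[DistinctPatient] = []
    for pseud in sorted(groups):
        group = groups[pseud]
        subtype, basis = resolve_diagnosis(group)
        age = _modal([e.age_at_genetic_diagnosis for e in group])
        patients.append(
            DistinctPatient(
                pseudonym=pseud,
                source_types=frozenset(e.source_type for e in group),
                disease_group=group[0].disease_group,
                final_subtype=subtype,
                classification_basis=basis,
                birth_year=group[0].birth_year,
                postal_region=_modal([e.postal_region for e in group]),
                age_at_genetic_diagnosis=age.value if age is not None else None,
                in_center_care=_modal([e.in_center_care for e in group]),
                n_entries=len(group),
            )
        )
    return patients


def overlap_cell(patient: DistinctPatient) -> OverlapCell:
    """Which of the 7 source-combination cells this patient falls in."""
    return OverlapCell.from_sources(patient.source_types)
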