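"""De-identified entry schema and CSV/JSON readers and writers.

One :class:`SourceEntry` is a single report of one patient by one reporting
site. The three source types ran slightly different questionnaires, which
the schema mirrors: only genetic institutes report an age-at-genetic-
diagnosis category, only the patient registry reports whether the patient
is regularly under specialist care, and genetic institutes do not classify
the clinical type of spinal muscular atrophy (they report the disease group
only).

Birth *year* — not the birth date, which is identifying and lives only on
the hashing side — travels with each entry; it is the incidence
denominator's stratification variable.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "SourceType",
    "DiseaseGroup",
    "Subtype",
    "DiagnosisAge",
    "Diagnosis",
    "SourceEntry",
    "EntryTable",
    "EntryValidationError",
    "ValidationIssue",
    "read_entries",
    "write_entries",
    "entry_from_row",
    "BIRTH_YEAR_MIN",
    "BIRTH_YEAR_MAX",
    "ENTRY_COLUMNS",
]

BIRTH_YEAR_MIN = 1995
BIRTH_YEAR_MAX = 2018


class SourceType(str, Enum):
    NEUROMUSCULAR_CENTER = "NEUROMUSCULAR_CENTER"
    GENETIC_INSTITUTE = "GENETIC_INSTITUTE"
    PATIENT_REGISTRY = "PATIENT_REGISTRY"


class DiseaseGroup(str, Enum):
    DYSTROPHINOPATHY = "DYSTROPHINOPATHY"
    SMA = "SMA"


class Subtype(str, Enum):
    DMD = "DMD"
    BMD = "BMD"
    SMA1 = "SMA1"
    SMA2 = "SMA2"
    SMA3 = "SMA3"
    UNSPECIFIED = "UNSPECIFIED"


#: Specific (non-UNSPECIFIED) subtypes belonging to each disease group.
SPECIFIC_SUBTYPES: dict[DiseaseGroup, frozenset[Subtype]] = {
    DiseaseGroup.DYSTROPHINOPATHY: frozenset({Subtype.DMD, Subtype.BMD}),
    DiseaseGroup.SMA: frozenset({Subtype.SMA1, Subtype.SMA2, Subtype.SMA3}),
}


class DiagnosisAge(str, Enum):
    """Age category at genetic diagnosis, as genetic institutes report it."""

    UNDER_6_MONTHS = "UNDER_6_MONTHS"
    M6_TO_18_MONTHS = "M6_TO_18_MONTHS"
    OVER_18_MONTHS = "OVER_18_MONTHS"


class Diagnosis(BaseModel):
    model_config = ConfigDict(frozen=True)

    disease_group: DiseaseGroup
    subtype: Subtype = Subtype.UNSPECIFIED

    @model_validator(mode="after")
    def _subtype_matches_group(self) -> "Diagnosis":
        if self.subtype is not Subtype.UNSPECIFIED and self.subtype not in SPECIFIC_SUBTYPES[self.disease_group]:
            raise ValueError(f"subtype {self.subtype.value} inconsistent with {self.disease_group.value}")
        return self


class SourceEntry(BaseModel):
    """One validated, de-identified report of one patient by one site."""

    model_config = ConfigDict(frozen=True)

    pseudonym: str
    source_type: SourceType
    source_id: str
    disease_group: DiseaseGroup
    subtype: Subtype = Subtype.UNSPECIFIED
    birth_year: int
    postal_region: Optional[int] = None
    age_at_genetic_diagnosis: Optional[DiagnosisAge] = None
    in_center_care: Optional[bool] = None

    @field_validator("pseudonym", "source_id")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("must be non-empty")
        return v

    @field_validator("birth_year")
    @classmethod
    def _birth_year_window(cls, v: int) -> int:
        if not (BIRTH_YEAR_MIN <= v <= BIRTH_YEAR_MAX):
            raise ValueError(f"birth_year {v} outside collection window {BIRTH_YEAR_MIN}-{BIRTH_YEAR_MAX}")
        return v

    @field_validator("postal_region")
    @classmethod
    def _region_digit(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not (0 <= v <= 9):
            raise ValueError("postal_region must be the single leading postal digit 0-9")
        return v

    @model_validator(mode="after")
    def _questionnaire_rules(self) -> "SourceEntry":
        Diagnosis(disease_group=self.disease_group, subtype=self.subtype)
        if self.age_at_genetic_diagnosis is not None and self.source_type is not SourceType.GENETIC_INSTITUTE:
            raise ValueError("age_at_genetic_diagnosis is collected only by genetic institutes")
        if self.in_center_care is not None and self.source_type is not SourceType.PATIENT_REGISTRY:
            raise ValueError("in_center_care is collected only by the patient registry")
        if (
            self.source_type is SourceType.GENETIC_INSTITUTE
            and self.disease_group is DiseaseGroup.SMA
            and self.subtype is not Subtype.UNSPECIFIED
        ):
            raise ValueError("SMA subtype is not collected from genetic institutes")
        return self


ENTRY_COLUMNS = [
    "pseudonym",
    "source_type",
    "source_id",
    "disease_group",
    "subtype",
    "birth_year",
    "postal_region",
    "age_at_genetic_diagnosis",
    "in_center_care",
]


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    message: str


class EntryValidationError(ValueError):
    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        first = issues[0]
        super().__init__(f"row {first.row}: {first.message} ({len(issues)} issue(s))")


@dataclass
class EntryTable:
    """An ordered collection of validated entries plus provenance.

    Identical rows are permitted — a site re-entering the same patient is a
    real phenomenon, resolved downstream by pseudonym grouping.
    """

    entries: list[SourceEntry]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def entry_from_row(row: dict[str, Any]) -> SourceEntry:
    """Build a SourceEntry from a flat string-keyed row (CSV cell or JSON
    object values); empty strings mean missing."""
    clean: dict[str, Any] = {}
    for key in ENTRY_COLUMNS:
        v = row.get(key)
        if v is None or (isinstance(v, str) and v == ""):
            continue
        if key == "birth_year" or key == "postal_region":
            clean[key] = int(v)
        elif key == "in_center_care":
            if isinstance(v, bool):
                clean[key] = v
            elif str(v).lower() in ("true", "false"):
                clean[key] = str(v).lower() == "true"
            else:
                raise ValueError(f"in_center_care must be true/false, got {v!r}")
        else:
            clean[key] = v
    unknown = set(row) - set(ENTRY_COLUMNS)
    if unknown:
        raise ValueError(f"unknown column(s): {sorted(unknown)}")
    return SourceEntry(**clean)


def _entry_to_row(entry: SourceEntry) -> dict[str, str]:
    row = {}
    for key in ENTRY_COLUMNS:
        v = getattr(entry, key)
        if v is None:
            row[key] = ""
        elif isinstance(v, bool):
            row[key] = "true" if v else "false"
        elif isinstance(v, Enum):
            row[key] = v.value
        else:
            row[key] = str(v)
    return row


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_entries(path: str | Path, format: Optional[str] = None, strict: bool = True) -> EntryTable:
    """Read and validate entries from CSV or JSON.

    In strict mode (default) the first invalid row aborts with
    :class:`EntryValidationError`. In lenient mode invalid rows are dropped,
    logged at WARNING level, and recorded in ``provenance["issues"]``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            raw_rows = [dict(r) for r in reader]
    elif fmt == "json":
        raw_rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(raw_rows, list):
            raise ValueError("JSON input must be an array of flat objects")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    entries: list[SourceEntry] = []
    issues: list[ValidationIssue] = []
    for i, row in enumerate(raw_rows):
        try:
            entries.append(entry_from_row(row))
        except (ValidationError, ValueError) as exc:
            issue = ValidationIssue(i, _summarize(exc))
            if strict:
                raise EntryValidationError([issue]) from exc
            logger.warning("dropping row %d: %s", i, issue.message)
            issues.append(issue)
    prov: dict[str, Any] = {"source_file": str(path), "rows_read": len(raw_rows)}
    if issues:
        prov["issues"] = issues
    return EntryTable(entries, prov)


def _summarize(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        err = exc.errors()[0]
        loc = ".".join(str(p) for p in err["loc"]) or "entry"
        return f"{loc}: {err['msg']}"
    return str(exc)


def write_entries(table: EntryTable, path: str | Path, format: Optional[str] = None) -> None:
    """Write entries to CSV (RFC-4180, UTF-8, header row) or JSON.

    Missing optional fields become empty cells in CSV and absent keys in
    JSON, so a write/read round trip reproduces the table field-for-field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=ENTRY_COLUMNS)
            writer.writeheader()
            for entry in table.entries:
                writer.writerow(_entry_to_row(entry))
    elif fmt == "json":
        objs = []
        for entry in table.entries:
            row = {k: v for k, v in _entry_to_row(entry).items() if v != ""}
            row["birth_year"] = entry.birth_year
            if entry.postal_region is not None:
                row["postal_region"] = entry.postal_region
            if entry.in_center_care is not None:
                row["in_center_care"] = entry.in_center_care
            objs.append(row)
        path.write_text(json.dumps(objs, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
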