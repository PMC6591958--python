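"""One-way pseudonymization of patient-identifying information.

Record linkage across independent reporting sources (clinical centers,
genetic laboratories, patient registries) works here by *exact equality* of
a linkage pseudonym derived from the patient's birth date and initials.
The derivation is

* **canonical** — both sites must hash byte-identical input, so PII is first
  normalized to a versioned canonical string ``"YYYY-MM-DD|GF"``;
* **keyed** — a deployment-wide secret salt partitions pseudonym space, so
  hashes from unrelated deployments can never be linked;
* **deliberately slow** — a password-style key-derivation function
  (PBKDF2-HMAC-SHA256 with ``2**cost`` iterations) makes offline
  brute-force enumeration of the small PII space expensive. Slowness is a
  functional requirement: the plausible input space (~24 years of dates x
  676 initial pairs, about 5.9 million strings) is tiny by cryptographic
  standards.

Raw PII exists only transiently inside this module; nothing downstream ever
sees a name or a full birth date.
"""

from __future__ import annotations

import base64
import hashlib
import unicodedata
from dataclasses import dataclass
from datetime import date
from typing import Any, Iterable, Mapping

__all__ = [
    "PIIRecord",
    "HashingConfig",
    "Pseudonym",
    "PIIValidationError",
    "HashingConfigError",
    "BatchFailure",
    "BatchResult",
    "canonicalize",
    "derive_pseudonym",
    "pseudonymize_batch",
    "DIALECT_V1",
    "MIN_COST",
    "MAX_COST",
]

DIALECT_V1 = "v1"
MIN_COST = 4
MAX_COST = 31

#: Key length of the derived pseudonym, in bytes. 24 bytes (192 bits) keeps
#: accidental collisions negligible over any realistic cohort.
_DKLEN = 24

_PII_FIELDS = ("birth_date", "given_name", "family_name")


class PIIValidationError(ValueError):
    """A PII field failed validation.

    Messages name the offending *field*, never its value — error text must
    be safe to log.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class HashingConfigError(ValueError):
    """The hashing configuration is unusable (bad cost, empty salt...)."""


@dataclass(frozen=True)
class PIIRecord:
    """Raw identifying fields; must never leave this module un-hashed."""

    birth_date: date
    given_name: str
    family_name: str

    @classmethod
    def from_strings(cls, birth_date: str, given_name: str, family_name: str) -> "PIIRecord":
        """Parse an ISO-8601 date string; invalid dates raise :class:`PIIValidationError`."""
        try:
            parsed = date.fromisoformat(str(birth_date).strip())
        except ValueError as exc:
            raise PIIValidationError("birth_date", "not a valid ISO calendar date") from exc
        return cls(parsed, given_name, family_name)


@dataclass(frozen=True)
class HashingConfig:
    """Deployment-wide hashing parameters.

    All sites contributing to one linkage run must share the identical
    (salt, cost, dialect_version) triple; changing any of the three yields a
    disjoint pseudonym space. The salt is a configured constant, never
    random: per-call random salts would break cross-site linkage.
    """

    salt: str
    cost: int = 10
    dialect_version: str = DIALECT_V1

    def __post_init__(self) -> None:
        if not self.salt:
            raise HashingConfigError("salt must be a non-empty deployment secret")
        if not (MIN_COST <= self.cost <= MAX_COST):
            raise HashingConfigError(
                f"cost {self.cost} outside supported range [{MIN_COST}, {MAX_COST}]"
            )
        if not self.dialect_version:
            raise HashingConfigError("dialect_version must be non-empty")


@dataclass(frozen=True)
class Pseudonym:
    """Opaque linkage token; equal iff derived from identical canonical PII
    under an identical :class:`HashingConfig`."""

    value: str


def _initial(name: str, field: str) -> str:
    """First Latin letter of a name after canonical decomposition.

    Diacritics are folded by NFKD decomposition followed by removal of
    combining marks; anything that is not an ASCII letter afterwards is
    stripped. A name with no Latin letter after folding is rejected rather
    than silently substituted — deterministic cross-site behavior beats
    permissiveness.
    """
    decomposed = unicodedata.normalize("NFKD", name)
    letters = [c for c in decomposed if not unicodedata.combining(c) and c.isalpha()]
    if not letters:
        raise PIIValidationError(field, "no letter remains after normalization")
    # first letter of the whole normalized string; no particle stripping
    # ("de Vries" -> D)
    first = letters[0].upper()
    if not ("A" <= first <= "Z"):
        raise PIIValidationError(field, "leading letter outside Latin range after folding")
    return first


def canonicalize(pii: PIIRecord) -> str:
    """Normalize a PII record to the dialect-v1 canonical string.

    Format: ``"YYYY-MM-DD|GF"`` with G/F the uppercased, diacritic-folded
    first letters of the given and family names. Idempotent on
    already-canonical single-letter names.
    """
    if not isinstance(pii.birth_date, date):
        raise PIIValidationError("birth_date", "must be a calendar date")
    g = _initial(pii.given_name, "given_name")
    f = _initial(pii.family_name, "family_name")
    return f"{pii.birth_date.isoformat()}|{g}{f}"


def derive_pseudonym(canonical: str, config: HashingConfig) -> Pseudonym:
    """Derive the linkage pseudonym from a canonical PII string.

    PBKDF2-HMAC-SHA256 with ``2**cost`` iterations over the canonical
    string, keyed by the deployment salt. Deterministic across runs and
    platforms; wall time doubles per unit of ``cost``.
    """
    if not (MIN_COST <= config.cost <= MAX_COST):
        raise HashingConfigError(f"unsupported cost {config.cost}")
    key = hashlib.pbkdf2_hmac(
        "sha256",
        password=f"{config.dialect_version}|{canonical}".encode("utf-8"),
        salt=hashlib.sha256(f"rarelink-linkage|{config.salt}".encode("utf-8")).digest(),
        iterations=2 ** config.cost,
        dklen=_DKLEN,
    )
    token = base64.urlsafe_b64encode(key).decode("ascii").rstrip("=")
    return Pseudonym(f"{config.dialect_version}${config.cost}${token}")


@dataclass(frozen=True)
class BatchFailure:
    """One rejected input row: its index and a PII-safe reason."""

    row: int
    field: str
    message: str


@dataclass
class BatchResult:
    entries: list[dict[str, Any]]
    failures: list[BatchFailure]


def pseudonymize_batch(
    rows: Iterable[Mapping[str, Any]], config: HashingConfig
) -> BatchResult:
    """Hash a batch of PII-bearing rows into de-identified rows.

    Each input row carries ``birth_date`` (ISO string or ``date``),
    ``given_name``, ``family_name`` plus arbitrary passthrough attribute
    columns. Output rows contain ``pseudonym``, a derived ``birth_year``
    (non-identifying, needed for incidence denominators) and the passthrough
    attributes; no PII field survives. Invalid rows are collected as
    :class:`BatchFailure` with their index; valid rows are still processed.
    """
    entries: list[dict[str, Any]] = []
    failures: list[BatchFailure] = []
    for i, row in enumerate(rows):
        try:
            bd = row["birth_date"]
            pii = (
                PIIRecord(bd, str(row["given_name"]), str(row["family_name"]))
                if isinstance(bd, date)
                else PIIRecord.from_strings(str(bd), str(row["given_name"]), str(row["family_name"]))
            )
            canonical = canonicalize(pii)
        except KeyError as exc:
            failures.append(BatchFailure(i, str(exc.args[0]), "missing PII field"))
            continue
        except PIIValidationError as exc:
            failures.append(BatchFailure(i, exc.field, str(exc).split(": ", 1)[-1]))
            continue
        out = {k: v for k, v in row.items() if k not in _PII_FIELDS}
        out["pseudonym"] = derive_pseudonym(canonical, config).value
        out["birth_year"] = pii.birth_date.year
        entries.append(out)
    return BatchResult(entries, failures)
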