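"""End-to-end composition: PII stream -> hashed entries -> distinct patients."""

from __future__ import annotations

from typing import Any, Iterable, Mapping

from .dedup_merge import DistinctPatient, build_distinct_patients
from .pii_hashing import BatchResult, HashingConfig, pseudonymize_batch
from .records_io import EntryTable, entry_from_row

__all__ = ["deidentify", "run_linkage"]


def deidentify(rows: Iterable[Mapping[str, Any]], config: HashingConfig) -> tuple[EntryTable, BatchResult]:
    """Hash a PII-bearing row stream and validate the de-identified entries.

    Returns the validated entry table together with the raw batch result
    (which carries per-row hashing failures, if any).
    """
    batch = pseudonymize_batch(rows, config)
    entries = [entry_from_row(r) for r in batch.entries]
    table = EntryTable(entries, provenance={"rows_in": len(batch.entries) + len(batch.failures)})
    return table, batch


def run_linkage(rows: Iterable[Mapping[str, Any]], config: HashingConfig) -> tuple[EntryTable, list[DistinctPatient]]:
    """The full linkage pipeline: hash, validate, de-duplicate."""
    table, _ = deidentify(rows, config)
    return table, build_distinct_patients(table)
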