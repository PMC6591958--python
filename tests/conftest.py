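from __future__ import annotations

import pytest

from rarelink.pii_hashing import HashingConfig
from rarelink.records_io import (
    DiseaseGroup,
    SourceEntry,
    SourceType,
    Subtype,
)


@pytest.fixture(scope="session")
def config() -> HashingConfig:
    """Low-cost hashing config: suites must stay fast; production keeps the
    slow default."""
    return HashingConfig(salt="unit-test-secret", cost=4)


def make_entry(
    pseudonym: str = "p1",
    source_type: SourceType = SourceType.NEUROMUSCULAR_CENTER,
    source_id: str = "NC01",
    disease_group: DiseaseGroup = DiseaseGroup.DYSTROPHINOPATHY,
    subtype: Subtype = Subtype.UNSPECIFIED,
    birth_year: int = 2005,
    **kwargs,
) -> SourceEntry:
    return SourceEntry(
        pseudonym=pseudonym,
        source_type=source_type,
        source_id=source_id,
        disease_group=disease_group,
        subtype=subtype,
        birth_year=birth_year,
        **kwargs,
    )


@pytest.fixture
def entry_factory():
    return make_entry
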