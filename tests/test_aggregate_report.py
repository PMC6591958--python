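"""Aggregate tables, printed-percentage arithmetic, and suppression safety."""

from __future__ import annotations

import itertools

import pytest

from rarelink.aggregate_report import (
    AggregateTable,
    genetic_only_diagnosis_age,
    overlap_summary,
    percentage,
    regional_distribution,
    registry_participation,
    subtype_distribution,
    suppress,
)
from rarelink.dedup_merge import ClassificationBasis, DistinctPatient
from rarelink.records_io import DiseaseGroup, SourceType, Subtype

C, G, R = (
    SourceType.NEUROMUSCULAR_CENTER,
    SourceType.GENETIC_INSTITUTE,
    SourceType.PATIENT_REGISTRY,
)


def make_patient(
    i: int,
    sources=frozenset({C}),
    disease=DiseaseGroup.DYSTROPHINOPATHY,
    subtype=Subtype.DMD,
    **kw,
) -> DistinctPatient:
    basis = kw.pop("classification_basis", ClassificationBasis.CENTER)
    if subtype is Subtype.UNSPECIFIED and basis is ClassificationBasis.CENTER:
        basis = ClassificationBasis.UNRESOLVED
    return DistinctPatient(
        pseudonym=f"p{i:05d}",
        source_types=frozenset(sources),
        disease_group=disease,
        final_subtype=subtype,
        classification_basis=basis,
        birth_year=kw.pop("birth_year", 2005),
        **kw,
    )


@pytest.mark.parametrize(
    "count, denom, expected",
    [
        (985, 1955, 50.4),
        (697, 1955, 35.7),
        (273, 1955, 14.0),
        (1038, 3242, 32.0),
        (0, 100, 0.0),
        (1, 1600, 0.1),  # exact half rounds up
        (100, 100, 100.0),
    ],
)
def test_percentage_rounds_half_up_to_one_decimal(count, denom, expected):
    assert percentage(count, denom) == expected


def test_percentage_rejects_bad_denominators():
    with pytest.raises(ValueError):
        percentage(1, 0)
    with pytest.raises(ValueError):
        percentage(5, 4)


def _patients_by_cells(cells: dict[frozenset, int], disease=DiseaseGroup.DYSTROPHINOPATHY):
    patients = []
    i = 0
    for sources, n in cells.items():
        for _ in range(n):
            patients.append(make_patient(i, sources=sources, disease=disease))
            i += 1
    return patients


def test_overlap_summary_by_source_count():
    patients = _patients_by_cells(
        {
            frozenset({C}): 500,
            frozenset({G}): 400,
            frozenset({R}): 85,
            frozenset({C, G}): 400,
            frozenset({C, R}): 200,
            frozenset({G, R}): 97,
            frozenset({C, G, R}): 273,
        }
    )
    agg = overlap_summary(patients, DiseaseGroup.DYSTROPHINOPATHY)
    assert agg.counts == {"1_SOURCE": 985, "2_SOURCES": 697, "3_SOURCES": 273}
    assert agg.denominator == 1955
    assert [agg.percent(l) for l in agg.counts] == [50.4, 35.7, 14.0]
    cells = overlap_summary(patients, DiseaseGroup.DYSTROPHINOPATHY, detail="cells")
    assert sum(cells.counts.values()) == 1955  # partition law


def test_overlap_summary_empty_scope_has_no_percentages():
    agg = overlap_summary([], DiseaseGroup.SMA)
    assert agg.total == 0
    assert agg.percent("1_SOURCE") is None


def test_overlap_summary_single_source_cohort():
    patients = [make_patient(i) for i in range(10)]
    agg = overlap_summary(patients)
    assert agg.percent("1_SOURCE") == 100.0


def test_subtype_distribution_with_restriction():
    sma_cr = [
        make_patient(i, sources=frozenset({C}), disease=DiseaseGroup.SMA, subtype=Subtype.SMA1)
        for i in range(273)
    ]
    sma_cr += [
        make_patient(1000 + i, sources=frozenset({R}), disease=DiseaseGroup.SMA, subtype=Subtype.SMA2)
        for i in range(485)
    ]
    genetic_only = [
        make_patient(
            5000 + i,
            sources=frozenset({G}),
            disease=DiseaseGroup.SMA,
            subtype=Subtype.UNSPECIFIED,
            classification_basis=ClassificationBasis.SINGLE_NONCENTER,
        )
        for i in range(529)
    ]
    agg = subtype_distribution(
        sma_cr + genetic_only, DiseaseGroup.SMA, restrict_to_sources={C, R}
    )
    assert agg.denominator == 758
    assert agg.percent("SMA1") == 36.0
    full = subtype_distribution(sma_cr + genetic_only, DiseaseGroup.SMA)
    assert full.denominator == 758 + 529


def test_subtype_distribution_all_unclassified():
    patients = [
        make_patient(
            i,
            subtype=Subtype.UNSPECIFIED,
            classification_basis=ClassificationBasis.UNRESOLVED,
        )
        for i in range(6)
    ]
    agg = subtype_distribution(patients, DiseaseGroup.DYSTROPHINOPATHY)
    assert agg.percent("UNSPECIFIED") == 100.0


def test_genetic_only_diagnosis_age_report():
    cohort = [
        make_patient(
            i,
            sources=frozenset({G}),
            disease=DiseaseGroup.SMA,
            subtype=Subtype.UNSPECIFIED,
            classification_basis=ClassificationBasis.SINGLE_NONCENTER,
            age_at_genetic_diagnosis="UNDER_6_MONTHS" if i < 320 else "OVER_18_MONTHS",
        )
        for i in range(529)
    ] + [
        make_patient(9000 + i, sources=frozenset({C}), disease=DiseaseGroup.SMA, subtype=Subtype.SMA1)
        for i in range(758)
    ]
    report = genetic_only_diagnosis_age(cohort)
    assert report.share.counts["GENETIC_ONLY"] == 529
    assert report.share.percent("GENETIC_ONLY") == 41.1
    assert report.ages.percent("UNDER_6_MONTHS") == 60.5


def test_genetic_only_empty():
    report = genetic_only_diagnosis_age([])
    assert report.share.counts["GENETIC_ONLY"] == 0
    assert report.ages.percent("UNDER_6_MONTHS") is None


def test_registry_participation_extremes():
    all_registry = [
        make_patient(i, sources=frozenset({R}), in_center_care=False) for i in range(8)
    ]
    stats = registry_participation(all_registry)
    assert stats["DMD"].participation_pct == 100.0
    no_registry = [make_patient(i) for i in range(8)]
    assert registry_participation(no_registry)["DMD"].participation_pct == 0.0


def test_registry_care_fraction():
    patients = [
        make_patient(i, sources=frozenset({C, R}), in_center_care=(i < 6)) for i in range(10)
    ]
    stats = registry_participation(patients)["DMD"]
    assert stats.n_registry == 10 and stats.care_pct == 60.0


def test_regional_distribution_rates():
    pop = {d: 1_000_000 for d in range(10)}
    patients = [make_patient(i, postal_region=7) for i in range(10)]
    patients.append(make_patient(99, postal_region=None))
    agg = regional_distribution(patients, pop)
    assert agg.counts["7"] == 10
    assert agg.extra["per_100k"]["7"] == 1.0
    assert agg.counts["UNKNOWN"] == 1
    # conservation: rates x population recover located patients
    total = sum(
        agg.extra["per_100k"][str(d)] * pop[d] / 100_000 for d in range(10)
    )
    assert total == pytest.approx(10)


def test_regional_distribution_requires_population_coverage():
    with pytest.raises(ValueError, match="digits 0-9"):
        regional_distribution([], {0: 100})


class TestSuppression:
    def test_cells_below_k_replaced_and_margin_protected(self):
        table = AggregateTable({"a": 12, "b": 3, "c": 40}, denominator=55)
        out = suppress(table, k=5)
        # the 3 is primary; a lone suppressed cell would be recoverable from
        # the margin, so the next-smallest (12) is complementarily hidden
        assert out.suppressed == {"b", "a"}
        released = out.released()
        assert list(released["count"][:3]) == ["<5", "<5", 40]

    def test_all_cells_at_or_above_k_unchanged(self):
        out = suppress(AggregateTable({"a": 7, "b": 6, "c": 5}, denominator=18), k=5)
        assert out.suppressed == frozenset()

    def test_zero_cells_are_released(self):
        out = suppress(AggregateTable({"a": 0, "b": 2}, denominator=2, margin_published=False), k=5)
        assert out.suppressed == {"b"}
        assert list(out.released()["count"]) == [0, "<5"]

    def test_forced_all_ones_pattern_is_protected(self):
        # hidden mass equal to the number of hidden cells would force each
        # hidden cell to 1; suppression must widen or drop the margin
        table = AggregateTable({"a": 12, "b": 1, "c": 1}, denominator=14)
        out = suppress(table, k=5)
        solutions = _solve(out)
        for label in out.suppressed:
            assert len(solutions[label]) > 1

    def test_nothing_left_to_hide_drops_margin(self):
        table = AggregateTable({"a": 1, "b": 0}, denominator=1)
        out = suppress(table, k=5)
        assert not out.margin_published

    def test_increasing_k_never_reveals(self):
        table = AggregateTable({"a": 3, "b": 6, "c": 11, "d": 0}, denominator=20)
        k5 = suppress(table, k=5)
        k7 = suppress(table, k=7)
        assert k5.suppressed <= k7.suppressed


def _solve(table: AggregateTable) -> dict[str, set[int]]:
    """Exhaustive attack: enumerate integer completions (each hidden cell
    >= 1) consistent with the published margin; collect feasible values."""
    hidden = sorted(table.suppressed)
    visible_sum = sum(n for l, n in table.counts.items() if l not in hidden)
    remainder = table.total - visible_sum
    feasible: dict[str, set[int]] = {l: set() for l in hidden}
    if not table.margin_published:
        # without a margin any value >= 1 is feasible; never unique
        for l in hidden:
            feasible[l] = {1, 2}
        return feasible
    for combo in itertools.product(range(1, remainder + 1), repeat=len(hidden)):
        if sum(combo) == remainder:
            for l, v in zip(hidden, combo):
                feasible[l].add(v)
    return feasible


@pytest.mark.parametrize("counts", [
    {"a": 3, "b": 9, "c": 140, "d": 2},
    {"a": 1, "b": 1, "c": 1},
    {"a": 4, "b": 5},
    {"a": 0, "b": 4, "c": 17, "d": 6, "e": 2, "f": 30},
])
def test_no_suppressed_cell_is_uniquely_recoverable(counts):
    out = suppress(AggregateTable(counts, denominator=sum(counts.values())), k=5)
    solutions = _solve(out)
    for label in out.suppressed:
        assert len(solutions[label]) > 1, label
    for label, n in out.counts.items():
        if label not in out.suppressed:
            assert not (1 <= n < 5)


def test_unrounded_percentages_conserve_mass():
    counts = {"a": 313, "b": 207, "c": 480}
    denom = sum(counts.values())
    exact = [100 * v / denom for v in counts.values()]
    assert sum(exact) == pytest.approx(100, abs=1e-9)
    table = AggregateTable(counts, denominator=denom)
    rounded = [table.percent(l) for l in counts]
    assert abs(sum(rounded) - 100) <= 0.1 * len(counts)
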