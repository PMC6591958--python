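"""Ground-truth cohort generator for end-to-end pipeline testing.

No real patient data ships with this package; instead this module draws a
synthetic population with the statistical structure of a multi-source
rare-disease collection effort:

* per birth year, disease counts are Binomial(live births, incidence);
* each patient is independently captured by each of the three source types
  with probabilities that depend on the true subtype and on the birth era —
  severe infantile spinal muscular atrophy (type 1) is captured mostly by
  genetic laboratories because many affected children die before reaching
  a specialist center or a registry, dystrophinopathy capture shifts from
  centers toward genetic confirmation in later birth years;
* registry capture is positively linked to specialist-center care via a
  boost factor (patients followed in a center are likelier to enroll);
* sources re-enter patients (within-source duplicates), a second center
  occasionally reports a different subtype (conflicts), non-center sources
  mis-report subtypes at a configurable rate, and patients can share a
  birth date and initials (forced PII collisions — the intrinsic
  false-merge limitation of exact-hash linkage).

Every draw flows from a single seed, so identical parameters reproduce the
cohort byte-for-byte. ``expected_overlap_fractions`` is the closed-form
counterpart of the capture model and serves as the oracle for end-to-end
recovery tests.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .dedup_merge import DistinctPatient, OverlapCell
from .pii_hashing import HashingConfig, PIIRecord, canonicalize, derive_pseudonym
from .records_io import DiagnosisAge, DiseaseGroup, SourceType, SPECIFIC_SUBTYPES, Subtype

__all__ = [
    "SimulationParams",
    "Cohort",
    "generate_cohort",
    "expected_overlap_fractions",
    "false_merge_rate",
    "DEFAULT_HASHING",
]

Era = Literal["early", "late"]

#: Test/simulation hashing configuration (low cost: slowness is pointless
#: against data we invented ourselves).
DEFAULT_HASHING = HashingConfig(salt="synthetic-cohort", cost=4)

_C, _G, _R = (
    SourceType.NEUROMUSCULAR_CENTER,
    SourceType.GENETIC_INSTITUTE,
    SourceType.PATIENT_REGISTRY,
)

# Capture probabilities per (true subtype, era). "early" is birth years
# before the disease's era cutoff. Registry values are the baseline for
# patients NOT under center care; the per-disease boost multiplies them for
# center-captured patients. Values calibrated so the mixture reproduces the
# qualitative multi-source pattern of a German neuromuscular collection:
# center-dominant dystrophinopathy ascertainment (stronger in early birth
# years), genetic-laboratory-dominant SMA ascertainment, weak registry
# coverage throughout, near-absent registry/center capture of early-era
# SMA type 1.
_DEFAULT_CAPTURE: dict[Subtype, dict[Era, dict[SourceType, float]]] = {
    Subtype.DMD: {
        "early": {_C: 0.68, _G: 0.32, _R: 0.26},
        "late": {_C: 0.54, _G: 0.47, _R: 0.24},
    },
    Subtype.BMD: {
        "early": {_C: 0.50, _G: 0.38, _R: 0.18},
        "late": {_C: 0.46, _G: 0.44, _R: 0.18},
    },
    Subtype.SMA1: {
        "early": {_C: 0.18, _G: 0.62, _R: 0.04},
        "late": {_C: 0.40, _G: 0.68, _R: 0.12},
    },
    Subtype.SMA2: {
        "early": {_C: 0.44, _G: 0.48, _R: 0.17},
        "late": {_C: 0.52, _G: 0.52, _R: 0.19},
    },
    Subtype.SMA3: {
        "early": {_C: 0.40, _G: 0.42, _R: 0.15},
        "late": {_C: 0.46, _G: 0.46, _R: 0.16},
    },
}

_DEFAULT_DIAGNOSIS_AGE: dict[Subtype, dict[DiagnosisAge, float]] = {
    Subtype.DMD: {
        DiagnosisAge.UNDER_6_MONTHS: 0.05,
        DiagnosisAge.M6_TO_18_MONTHS: 0.15,
        DiagnosisAge.OVER_18_MONTHS: 0.80,
    },
    Subtype.BMD: {
        DiagnosisAge.UNDER_6_MONTHS: 0.01,
        DiagnosisAge.M6_TO_18_MONTHS: 0.09,
        DiagnosisAge.OVER_18_MONTHS: 0.90,
    },
    Subtype.SMA1: {
        DiagnosisAge.UNDER_6_MONTHS: 0.95,
        DiagnosisAge.M6_TO_18_MONTHS: 0.04,
        DiagnosisAge.OVER_18_MONTHS: 0.01,
    },
    Subtype.SMA2: {
        DiagnosisAge.UNDER_6_MONTHS: 0.10,
        DiagnosisAge.M6_TO_18_MONTHS: 0.60,
        DiagnosisAge.OVER_18_MONTHS: 0.30,
    },
    Subtype.SMA3: {
        DiagnosisAge.UNDER_6_MONTHS: 0.02,
        DiagnosisAge.M6_TO_18_MONTHS: 0.18,
        DiagnosisAge.OVER_18_MONTHS: 0.80,
    },
}

# Initial letters are drawn from skewed frequency vectors over the full
# A-Z range (roughly echoing German name-initial frequencies), then a name
# carrying that initial is picked from a small pool (the bare letter serves
# as a fallback name). Skew makes the natural PII-collision rate a
# controlled function of the letter-pair frequencies, as it is in reality.
_GIVEN_NAMES = {
    "A": ["Anna", "Alexander", "Amelie"], "B": ["Ben", "Berat"], "C": ["Clara", "Can"],
    "D": ["David", "Deniz"], "E": ["Emma", "Elias"], "F": ["Finn", "Frieda"],
    "H": ["Hannah", "Henri"], "J": ["Jonas", "Julia", "Jörg"], "K": ["Katharina", "Karl"],
    "L": ["Lukas", "Lena"], "M": ["Maximilian", "Marie"], "N": ["Noah", "Nele"],
    "P": ["Paul", "Pia"], "S": ["Sophie", "Samuel"], "T": ["Tim", "Theresa"],
}
_FAMILY_NAMES = {
    "B": ["Becker", "Braun"], "F": ["Fischer"], "H": ["Hoffmann", "Hartmann"],
    "K": ["Klein", "Köhler"], "M": ["Müller", "Meyer"], "N": ["Neumann"],
    "R": ["Richter"], "S": ["Schmidt", "Schäfer"], "V": ["Vogel"],
    "W": ["Wagner", "Weber"], "Z": ["Zimmermann"],
}
_LETTERS = [chr(c) for c in range(ord("A"), ord("Z") + 1)]
_GIVEN_FREQ = np.array(
    [8, 4, 3, 4, 6, 4, 3, 5, 2, 7, 5, 7, 9, 4, 1, 3, 0.2, 3, 7, 4, 1, 2, 2, 0.3, 0.5, 1],
    dtype=float,
)
_FAMILY_FREQ = np.array(
    [2, 8, 2, 4, 2, 5, 6, 9, 1, 2, 9, 5, 8, 3, 1, 4, 0.2, 5, 12, 4, 1, 2, 7, 0.1, 0.2, 2],
    dtype=float,
)


def _normalized(probs: dict) -> dict:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {total}")
    return probs


class SimulationParams(BaseModel):
    """Generator configuration; defaults are the package's study conditions."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    years: tuple[int, int] = (1995, 2018)
    births_per_year: int = 730_000
    incidence_per_10k: dict[DiseaseGroup, float] = {
        DiseaseGroup.DYSTROPHINOPATHY: 1.35,
        DiseaseGroup.SMA: 0.95,
    }
    subtype_probs: dict[DiseaseGroup, dict[Subtype, float]] = {
        DiseaseGroup.DYSTROPHINOPATHY: {Subtype.DMD: 0.77, Subtype.BMD: 0.23},
        DiseaseGroup.SMA: {Subtype.SMA1: 0.45, Subtype.SMA2: 0.33, Subtype.SMA3: 0.22},
    }
    era_cutoff: dict[DiseaseGroup, int] = {
        DiseaseGroup.DYSTROPHINOPATHY: 2000,
        DiseaseGroup.SMA: 2012,
    }
    capture_probs: dict[Subtype, dict[Era, dict[SourceType, float]]] = _DEFAULT_CAPTURE
    registry_center_boost: dict[DiseaseGroup, float] = {
        DiseaseGroup.DYSTROPHINOPATHY: 1.56,
        DiseaseGroup.SMA: 3.26,
    }
    dup_within_source_prob: float = 0.08
    center_conflict_prob: float = 0.02
    noncenter_subtype_error_prob: float = 0.05
    pii_collision_prob: float = 0.0015
    diagnosis_age_probs: dict[Subtype, dict[DiagnosisAge, float]] = _DEFAULT_DIAGNOSIS_AGE
    region_weights: tuple[float, ...] = (0.07, 0.09, 0.08, 0.12, 0.12, 0.10, 0.10, 0.12, 0.12, 0.08)
    n_centers: int = 32
    n_genetic_institutes: int = 12

    @field_validator(
        "dup_within_source_prob",
        "center_conflict_prob",
        "noncenter_subtype_error_prob",
        "pii_collision_prob",
    )
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("probability outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _valid(self) -> "SimulationParams":
        y0, y1 = self.years
        if y0 > y1:
            raise ValueError("years must be (first, last) with first <= last")
        if self.births_per_year <= 0:
            raise ValueError("births_per_year must be positive")
        for dist in self.subtype_probs.values():
            _normalized(dist)
        for dist in self.diagnosis_age_probs.values():
            _normalized(dist)
        _normalized({i: w for i, w in enumerate(self.region_weights)})
        for table in self.capture_probs.values():
            for era in table.values():
                for p in era.values():
                    if not (0.0 <= p <= 1.0):
                        raise ValueError("capture probability outside [0, 1]")
        for b in self.registry_center_boost.values():
            if b < 0:
                raise ValueError("registry boost must be non-negative")
        return self

    def lossless(self) -> "SimulationParams":
        """The identity limit: every patient captured by every source, no
        duplicates, no conflicts, no reporting errors, no PII collisions."""
        full = {
            st: {era: {s: 1.0 for s in SourceType} for era in ("early", "late")}
            for st in self.capture_probs
        }
        return self.model_copy(
            update=dict(
                capture_probs=full,
                registry_center_boost={d: 1.0 for d in self.registry_center_boost},
                dup_within_source_prob=0.0,
                center_conflict_prob=0.0,
                noncenter_subtype_error_prob=0.0,
                pii_collision_prob=0.0,
            )
        )


@dataclass
class Cohort:
    """Ground truth plus the PII-bearing entry stream the pipeline consumes."""

    truth: pd.DataFrame
    entries: list[dict]
    params: SimulationParams
    hashing: HashingConfig


def _era(params: SimulationParams, disease: DiseaseGroup, year: int) -> Era:
    return "early" if year < params.era_cutoff[disease] else "late"


def _registry_prob(params, disease, subtype, era, center_captured) -> float:
    base = params.capture_probs[subtype][era][_R]
    if center_captured:
        return min(1.0, params.registry_center_boost[disease] * base)
    return base


def generate_cohort(
    params: SimulationParams, hashing: HashingConfig = DEFAULT_HASHING
) -> Cohort:
    """Draw a full two-disease cohort and its multi-source entry stream."""
    rng = np.random.default_rng(params.seed)
    y0, y1 = params.years
    truth_rows: list[dict] = []
    entries: list[dict] = []
    pid = 0
    # canonical (date, initials) keys already used, per disease. Within a
    # disease, reuse is a genuine false merge (natural or forced); across
    # diseases it would surface downstream as a mixed-disease integrity
    # error rather than a silent merge, so the generator resamples it away
    # and leaves that failure mode to dedicated unit tests.
    pii_keys: dict[DiseaseGroup, set[tuple[str, str, str]]] = {}

    for disease in sorted(params.incidence_per_10k, key=lambda d: d.value):
        rate = params.incidence_per_10k[disease] / 10_000.0
        subtypes = sorted(params.subtype_probs[disease], key=lambda s: s.value)
        sub_p = np.array([params.subtype_probs[disease][s] for s in subtypes])
        cohort_pii: list[tuple[str, str, str]] = []  # for forced collisions
        own_keys = pii_keys.setdefault(disease, set())
        other_keys = [ks for d, ks in pii_keys.items() if d is not disease]

        for year in range(y0, y1 + 1):
            n = rng.binomial(params.births_per_year, rate)
            era = _era(params, disease, year)
            for _ in range(n):
                subtype = subtypes[rng.choice(len(subtypes), p=sub_p)]
                days = 366 if calendar.isleap(year) else 365
                while True:
                    birth = date(year, 1, 1) + timedelta(days=int(rng.integers(days)))
                    gl, given = _pick_name(rng, _GIVEN_FREQ, _GIVEN_NAMES)
                    fl, family = _pick_name(rng, _FAMILY_FREQ, _FAMILY_NAMES)
                    key = (birth.isoformat(), gl, fl)
                    if not any(key in ks for ks in other_keys):
                        break
                birth_iso = birth.isoformat()
                if cohort_pii and rng.random() < params.pii_collision_prob:
                    birth_iso, given, family = cohort_pii[int(rng.integers(len(cohort_pii)))]
                    key = (birth_iso, given[0].upper(), family[0].upper())
                cohort_pii.append((birth_iso, given, family))
                own_keys.add(key)
                region = int(rng.choice(10, p=np.asarray(params.region_weights)))

                cap = params.capture_probs[subtype][era]
                captured_c = rng.random() < cap[_C]
                captured_g = rng.random() < cap[_G]
                captured_r = rng.random() < _registry_prob(params, disease, subtype, era, captured_c)

                pseud = derive_pseudonym(
                    canonicalize(PIIRecord(date.fromisoformat(birth_iso), given, family)),
                    hashing,
                ).value
                captured = [
                    s.value
                    for s, c in ((_C, captured_c), (_G, captured_g), (_R, captured_r))
                    if c
                ]
                truth_rows.append(
                    dict(
                        patient_id=pid,
                        disease_group=disease.value,
                        true_subtype=subtype.value,
                        birth_date=birth_iso,
                        given_name=given,
                        family_name=family,
                        birth_year=int(birth_iso[:4]),
                        postal_region=region,
                        captured_by=";".join(captured),
                        in_center_care=captured_c,
                        pseudonym=pseud,
                    )
                )
                entries.extend(
                    _emit_entries(
                        rng, params, disease, subtype, birth_iso, given, family,
                        region, captured_c, captured_g, captured_r,
                    )
                )
                pid += 1

    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    return Cohort(pd.DataFrame(truth_rows), entries, params, hashing)


def _pick_name(rng, freq, pool) -> tuple[str, str]:
    letter = _LETTERS[rng.choice(len(_LETTERS), p=freq / freq.sum())]
    names = pool.get(letter, [letter])
    return letter, names[int(rng.integers(len(names)))]


def _other_specific(rng, disease: DiseaseGroup, subtype: Subtype) -> Subtype:
    others = sorted(SPECIFIC_SUBTYPES[disease] - {subtype}, key=lambda s: s.value)
    return others[int(rng.integers(len(others)))]


def _emit_entries(
    rng, params, disease, subtype, birth_iso, given, family, region,
    captured_c, captured_g, captured_r,
) -> list[dict]:
    base = dict(
        birth_date=birth_iso,
        given_name=given,
        family_name=family,
        disease_group=disease.value,
        birth_year=int(birth_iso[:4]),
    )
    out: list[dict] = []

    def push(entry: dict) -> None:
        out.append(entry)
        if rng.random() < params.dup_within_source_prob:
            out.append(dict(entry))

    if captured_c:
        site = f"NC{int(rng.integers(params.n_centers)):02d}"
        push({**base, "source_type": _C.value, "source_id": site,
              "subtype": subtype.value, "postal_region": region,
              "age_at_genetic_diagnosis": None, "in_center_care": None})
        if rng.random() < params.center_conflict_prob:
            other_site = f"NC{int((int(site[2:]) + 1 + rng.integers(params.n_centers - 1)) % params.n_centers):02d}"
            push({**base, "source_type": _C.value, "source_id": other_site,
                  "subtype": _other_specific(rng, disease, subtype).value,
                  "postal_region": region,
                  "age_at_genetic_diagnosis": None, "in_center_care": None})
    if captured_g:
        site = f"GI{int(rng.integers(params.n_genetic_institutes)):02d}"
        if disease is DiseaseGroup.SMA:
            reported = Subtype.UNSPECIFIED  # clinical SMA type not collected here
        elif rng.random() < params.noncenter_subtype_error_prob:
            reported = _other_specific(rng, disease, subtype)
        else:
            reported = subtype
        ages = sorted(params.diagnosis_age_probs[subtype], key=lambda a: a.value)
        age_p = np.array([params.diagnosis_age_probs[subtype][a] for a in ages])
        age = ages[rng.choice(len(ages), p=age_p)]
        push({**base, "source_type": _G.value, "source_id": site,
              "subtype": reported.value, "postal_region": None,
              "age_at_genetic_diagnosis": age.value, "in_center_care": None})
    if captured_r:
        reported = (
            _other_specific(rng, disease, subtype)
            if rng.random() < params.noncenter_subtype_error_prob
            else subtype
        )
        push({**base, "source_type": _R.value,
              "source_id": "REG-DMD" if disease is DiseaseGroup.DYSTROPHINOPATHY else "REG-SMA",
              "subtype": reported.value, "postal_region": region,
              "age_at_genetic_diagnosis": None, "in_center_care": bool(captured_c)})
    return out


def expected_overlap_fractions(
    params: SimulationParams, disease_group: Optional[DiseaseGroup] = None
) -> dict[OverlapCell, float]:
    """Closed-form cell probabilities of the capture model.

    Under the generator's assumption — captures conditionally independent
    given subtype and era, apart from the registry-given-center boost — the
    probability of a source subset S is the product of capture/no-capture
    terms, marginalized over the subtype and era mixture and renormalized
    over the 7 non-empty subsets (patients captured by nobody are
    invisible). With ``disease_group=None`` the mixture spans both diseases
    weighted by their expected patient counts.
    """
    y0, y1 = params.years
    n_years = y1 - y0 + 1
    diseases = (
        [disease_group]
        if disease_group is not None
        else sorted(params.incidence_per_10k, key=lambda d: d.value)
    )
    unnorm: dict[OverlapCell, float] = {cell: 0.0 for cell in OverlapCell}
    for disease in diseases:
        w_disease = params.incidence_per_10k[disease]
        cutoff = params.era_cutoff[disease]
        f_early = min(max((cutoff - y0) / n_years, 0.0), 1.0)
        for subtype, p_sub in params.subtype_probs[disease].items():
            for era, f_era in (("early", f_early), ("late", 1.0 - f_early)):
                if f_era == 0.0:
                    continue
                w = w_disease * p_sub * f_era
                cap = params.capture_probs[subtype][era]
                pc, pg = cap[_C], cap[_G]
                for cell in OverlapCell:
                    s = cell.value
                    has_c = _C in s
                    pr = _registry_prob(params, disease, subtype, era, has_c)
                    prob = (
                        (pc if has_c else 1 - pc)
                        * (pg if _G in s else 1 - pg)
                        * (pr if _R in s else 1 - pr)
                    )
                    unnorm[cell] += w * prob
    total = sum(unnorm.values())
    if total == 0.0:
        raise ValueError("capture probabilities leave no patient observable")
    return {cell: v / total for cell, v in unnorm.items()}


def false_merge_rate(truth: pd.DataFrame, patients: list[DistinctPatient]) -> float:
    """Fraction of observed truth patients whose pseudonym is shared with a
    *different* truth patient — the intrinsic false-merge rate of
    exact-hash linkage on (birth date, initials)."""
    observed = truth[truth["captured_by"] != ""]
    if len(observed) == 0:
        return 0.0
    pipeline_pseuds = {p.pseudonym for p in patients}
    truth_pseuds = set(observed["pseudonym"])
    if truth_pseuds != pipeline_pseuds:
        raise ValueError("truth table does not correspond to this pipeline run")
    counts = observed["pseudonym"].value_counts()
    merged = observed["pseudonym"].map(counts).gt(1).sum()
    return float(merged / len(observed))
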