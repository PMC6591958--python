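# Methods

## Linkage model

Two reports refer to the same patient exactly when their linkage
pseudonyms are equal. The pseudonym is a keyed, slow, one-way hash of a
*canonical* PII string; there is no probabilistic or fuzzy matching
(phonetic codes, edit distances) anywhere in the pipeline. This buys
reproducibility and privacy at the cost of two intrinsic error modes:

* **false merges** — two individuals sharing a birth date and both
  initials receive one pseudonym. This is a property of the method, not a
  bug; the synthetic generator measures it (`false_merge_rate`), and under
  default conditions it sits near 0.2–0.3% of patients.
* **false splits** — the same individual entered with inconsistent PII
  (name variants changing the initial, wrong birth date) receives two
  pseudonyms. The canonicalization dialect minimizes the avoidable part;
  the unavoidable part is not modelled.

### Canonical dialect v1

`"YYYY-MM-DD|GF"`: ISO date, then the first letters of the given and
family names after NFKD decomposition, removal of combining marks, and
uppercasing ("Jörg Müller" → `JM`, "anna-lena de Vries" → `AD`). No
particle stripping — the first letter of the whole normalized string is
used, because the simplest rule is the one two independent sites apply
identically. A name whose first letter does not fold into A–Z is rejected
rather than silently transliterated: a deterministic error beats a
locale-dependent guess. The dialect tag is part of the hash input, so a
future rule change partitions pseudonym space instead of producing silent
mismatches.

### Key derivation

PBKDF2-HMAC-SHA256 over the dialect-prefixed canonical string, keyed by a
SHA-256-stretched deployment salt, with `2**cost` iterations and a
24-byte output. Properties relied on downstream: determinism across
platforms, salt separation (unrelated deployments cannot link), and wall
time doubling per cost unit. The cost default is 10 (~10^3 iterations);
test and simulation configurations use the minimum cost 4, since slowness
defends real PII, not synthetic data. The salt must be supplied — a
per-call random salt, the usual password-hashing default, would break
cross-site linkage, which is why the generic password-hashing API is not
used directly.

## De-duplication and conflict resolution

Entries group by exact pseudonym. Within a group, birth years must agree
(the hash input contains the full date, so disagreement proves a dialect
or data-entry fault and raises an integrity error rather than producing a
silent half-merge). Subtype precedence:

1. ≥ 2 distinct specific subtypes among neuromuscular-center entries →
   unclassified (`UNRESOLVED`). A single center contradicting itself is
   treated the same way — it is no more trustworthy than two centers
   disagreeing.
2. One specific center subtype → that subtype (`CENTER`), overriding any
   number of non-center reports.
3. Otherwise, specific subtypes from non-center sources: one reporting
   site → `SINGLE_NONCENTER`; several concordant sites →
   `CONCORDANT_NONCENTER`; conflicting sites → `UNRESOLVED`. The rule
   never invents a subtype.

Attribute merge: postal region, diagnosis-age category and the
in-center-care flag are taken as the modal value over the entries of the
source type that collects them; ties resolve to missing
(minimal-information rule). Output order is sorted by pseudonym, so
results are invariant to entry order.

## Aggregate disclosure control

Released tables apply k-threshold suppression (default k = 5): cells
counting 1 to k−1 individuals are replaced by `"<5"`. Zeros are released —
a zero describes no individual. Because a published row total would let a
reader reconstruct a lone hidden cell, suppression iterates: while the
hidden cells are uniquely solvable from the margin (a single hidden cell,
or hidden mass equal to the number of hidden cells, forcing all ones), the
next-smallest positive visible cell is hidden too; if nothing visible
remains, the margin itself is withheld. The complementary step goes beyond
the bare minimum-group-size rule; it is needed for the released tables to
withstand exhaustive integer back-calculation, which the test suite
performs on every released row. Setting `margin_published=False` on a
table reproduces bare-threshold behavior.

Percentages are rounded half-up to one decimal (incidences to two); the
unrounded values over a partition sum to 100 exactly, the rounded ones to
within 0.1 per cell.

## Incidence

Incidence for birth year *y* is `per × n_y / births_y` with `births_y`
live births of that calendar year — the only denominator consistent with
stratifying ascertained patients by birth year against natality data. The
DMD series counts only patients *resolved* to the Duchenne subtype
(excluding Becker and unclassified dystrophinopathies); the SMA series
counts the whole disease group. Peak lookup breaks ties toward the
earliest year. All estimates are minimal incidences: with source coverage
below 1 the estimator is biased downward by construction, which the test
suite asserts directionally; in the lossless simulation limit it is
unbiased.

Advisory under-ascertainment flags mark the last two birth years before
the end of collection and any year where more than 80% of patients were
seen by a single source alone.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:

* **Scale.** 24 birth years (1995–2018), 730,000 live births/year,
  disease incidence 1.35 per 10,000 births (dystrophinopathy, subtype mix
  77% DMD / 23% BMD) and 0.95 per 10,000 (SMA, mix 45/33/22% types 1–3 —
  type 1 deliberately above its clinically observed share, since severe
  infantile disease is under-ascertained by clinical sources). Yearly
  patient counts are Binomial(births, rate); a default run yields ≈ 1,900
  dystrophinopathy and ≈ 1,300 SMA distinct patients.
* **Capture model.** Each patient is captured by each source with a
  probability depending on true subtype and birth era (dystrophinopathy
  era cutoff 2000, SMA cutoff 2012): centers dominate dystrophinopathy
  ascertainment, genetic laboratories dominate SMA, and early-era SMA
  type 1 has near-zero center/registry capture (high infant mortality).
  Registry capture is boosted for center-captured patients (boost 1.56 /
  3.26), reflecting that center care drives registry enrollment. Baseline
  values were calibrated by least squares so the mixture reproduces the
  published marginal overlap pattern of the German collection
  (single-source ≈ 50%/62%, registry participation ≈ 39%/29%,
  center-care-given-registry ≈ 66%/63%); they are illustrative defaults,
  not inferred truth. Conditional independence given subtype and era
  cannot reproduce every printed marginal simultaneously — the three-source
  overlap comes out near 11% where the real collection printed 14.0% —
  which is why end-to-end tests compare the pipeline against the
  generator's own closed form (`expected_overlap_fractions`, exact under
  the model) rather than against the printed values.
* **Noise.** Within-source duplicate entry 8%; a second center reporting
  a different subtype 2%; non-center subtype misreport 5%; forced PII
  collision 0.15% per patient (copying an earlier same-cohort patient's
  birth date and name — approximately the natural rate implied by German
  name-initial frequencies at these cohort sizes). Initial letters are
  drawn from skewed A–Z frequency tables, so natural collisions occur on
  top. Cross-disease PII reuse is resampled away: downstream it would
  surface as a detectable mixed-disease integrity error, not a silent
  merge, and that failure mode is covered by dedicated unit tests instead.
* **Reporting semantics.** Genetic laboratories report no clinical SMA
  type and no postal region but an age-at-diagnosis category (type 1
  concentrated under 6 months, p = 0.95); the registry reports the
  in-center-care flag as the truth of center capture.

What the generator does **not** emulate: name-variant false splits,
survival/loss to follow-up beyond its ascertainment consequence, regional
reporting heterogeneity, and any dependence between sources beyond the
registry-center boost. Passing recovery tests therefore demonstrate
correctness of the linkage arithmetic under the stated capture model, not
completeness of real-world ascertainment.

## Problem sizes and numerical choices

Test and acceptance runs use the full default scale (≈ 3,200 distinct
patients; seconds of runtime) for end-to-end checks, scaled-down births
(8,000–250,000/year) for identity and recovery checks, and 2,000,000/year
for the tight Monte-Carlo comparison (≈ 32,000 patients). Stochastic
assertions use 3 standard-error bands around exact expectations. Rounding
is decimal half-up throughout (matching how such tables are customarily
printed); modal-attribute ties and peak-incidence ties resolve to missing
and to the earliest year respectively; hashing cost in tests is 4.

## Known limitations

* Linkage quality is bounded by PII quality; the false-split rate of real
  data entry is unknown and unmodelled.
* The suppression solver-resistance guarantee is per released row with a
  published margin; cross-table attacks combining several releases of the
  same cohort at different groupings are out of scope.
* Incidence for recent birth years is structurally underestimated; the
  advisory flags mark, but do not correct, this. Capture–recapture
  completeness correction would be the natural extension and is not
  implemented.
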