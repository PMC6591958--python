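# rarelink

Privacy-preserving record linkage and minimal-incidence estimation for
rare-disease surveillance across fragmented reporting sources.

## The problem

Countries without mandatory central registration see the same rare-disease
patient reported by several uncoordinated sources — specialist clinical
centers, genetic diagnostic laboratories, voluntary patient registries —
and by none of them reliably. Aggregating such collections double-counts
patients unless records can be linked, but data-protection rules forbid
pooling names and birth dates. `rarelink` implements the standard
resolution: each reporting site derives, locally, a deterministic one-way
pseudonym

```
h = KDF(salt, "YYYY-MM-DD|GF")
```

from the patient's birth date and the initials *G*, *F* of given and family
name (uppercased, diacritic-folded). Only `h` and non-identifying
attributes leave the site. Equality of pseudonyms across sites *is* the
linkage: entries sharing `h` collapse to one **distinct patient**. The KDF
is keyed by a deployment-wide secret salt and is deliberately slow
(PBKDF2-HMAC-SHA256 with 2^cost iterations), because the PII space —
roughly 8,766 dates × 676 initial pairs ≈ 5.9 million strings — is small
enough that a fast hash could be brute-forced offline.

On top of the linkage layer the package provides:

* **conflict resolution** — when sources disagree on the subtype
  (Duchenne vs. Becker muscular dystrophy; spinal muscular atrophy types
  1–3), the clinical-center diagnosis takes precedence; two disagreeing
  centers leave the patient unclassified;
* **aggregate export under k-anonymity** — released tables suppress any
  cell counting 1–4 individuals (k = 5), with complementary suppression so
  hidden cells cannot be back-calculated from published margins;
* **minimal incidence** — per birth year, distinct patients over live
  births (per 10,000): a lower bound, since patients missed by all sources
  are invisible;
* **a synthetic cohort generator** — ground-truth populations with
  realistic multi-source capture structure (era- and subtype-dependent,
  e.g. infantile SMA captured almost only by genetic laboratories), within-
  source duplicates, subtype conflicts and PII collisions, plus the
  closed-form overlap expectations the pipeline is tested against.

## Worked example

```bash
rarelink simulate --seed 3 --out-truth truth.csv --out-entries entries_pii.csv
rarelink hash --in entries_pii.csv --out entries_hashed.csv --config config.yaml
rarelink dedupe --in entries_hashed.csv --out patients.csv
rarelink aggregate --in entries_hashed.csv --report overlap --disease SMA --out overlap.csv
```

prints

```
4007 patients, 5366 entries
5366 entries hashed, 0 rejected
5366 entries -> 3125 distinct patients
```

and `overlap.csv` contains

```
label,count,percent
1_SOURCE,738,60.4
2_SOURCES,367,30.0
3_SOURCES,117,9.6
TOTAL,1222,
```

i.e. of 1,222 distinct synthetic SMA patients, 60.4% were reported by a
single source, 30.0% by two and 9.6% by all three — the overlap pattern
that motivates multi-source ascertainment: no single source comes close to
full coverage. The same library calls are available in Python
(`rarelink.run_linkage`, `rarelink.overlap_summary`, ...).

`config.yaml` holds the deployment hashing key:

```yaml
hashing:
  salt: demo-deployment-secret
  cost: 6        # 2^cost PBKDF2 iterations; production default is 10
  dialect: v1
```

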