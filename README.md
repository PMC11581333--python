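# oudharmony

A harmonization toolkit for multi-study opioid-use-disorder (OUD)
clinical-trial data. It ingests raw per-study bundles in three emulated
trial dialects — a methadone-vs-buprenorphine outpatient study, a
two-phase prescription-opioid buprenorphine study, and an inpatient
XR-naltrexone-vs-buprenorphine study — applies documented cleaning rules
and concept crosswalks, and emits a tidy relational database of 23
patient-level tables plus 3 metadata tables, with a machine-readable
codebook and a complete audit trail of every correction.

It is written for biostatisticians and data scientists who need to merge
heterogeneous substance-use trial data into a common data model, and for
methodologists studying the harmonization process itself: a first-class
synthetic-data module generates realistic three-dialect bundles with
*injected, ledgered errors*, so every cleaning rule can be scored against
known ground truth.

## The data model and the cleaning rules

Every patient-level table is keyed by `who` (a synthetic subject integer),
event tables carry `when` (integer days relative to consent, day 0 =
consent), and drug or concept values live in a single `what` column —
no `heroin_day1 … heroin_day7` column families. Binary indicators are
verb-prefixed (`is_male`) and coded 0/1. Study weeks are anchored on the
randomization date: days 0–6 after randomization are Week 1, days 7–13
Week 2, so week = ⌊d/7⌋ + 1.

The substantive rules implemented:

- **Free-text drugs** — spelling variants ("extacy"), compound entries
  ("Vicodin/Percocet") and dose text ("adderall 5 mg") canonicalize
  through a shipped lexicon; canonical drugs group into harmonized
  categories (crack → Cocaine, a nonspecific "opiates" item → Heroin,
  oxycodone → Opioid).
- **Alcohol quantities** — free-text daily amounts parse into standard
  drinks (12 oz beer = 5 oz wine = 1.5 oz spirits = 1 drink; a half
  gallon of spirits is 42⅔ drinks), so "1/2 12oz beer" → 0.5 and
  "6pk beer & 1/2 gal. rum" → 49; ambiguous "many"-type phrases code as
  5; missing amounts are imputed from a subject's consistent pattern.
- **Withdrawal** — COWS and SOWS totals cross-walk onto one ordinal
  severity: severe (COWS ≥ 25, SOWS ≥ 21), moderate (COWS ≥ 13,
  SOWS ≥ 11), mild (COWS ≥ 5, SOWS ≥ 1), else none; the closest
  measurements before/after first dose feed `withdrawal_pre_post`.
- **Urine screens** — unclear/invalid/not-assessed results count
  negative; opiate assays at 300 and 2000 ng/mL merge into one
  any-positive flag; duplicate same-date panels resolve through a
  deterministic cascade (justifying note → entry-timestamp repair →
  end-of-study-copy collapse → keep-all with an ambiguity flag); the
  `uds` table excludes the prescribed treatment drug, which stays in
  `all_drugs`.
- **Dates** — year typos, off-by-one survey dates and day-digit
  transpositions are repaired only when exactly one candidate fits the
  context (study window, expected week, recall-period anchor); anything
  ambiguous is flagged, never guessed.
- **Doses** — weekly logs expand to days, same-day split logs sum, and an
  isolated single-day record of the *other* study drug amid assigned
  treatment is relabeled to the randomized assignment.
- **Risky behaviors** — categorical frequencies convert to days/30
  (not at all = 0, a few times = 5, a few times each week = 15,
  every day = 30); IV-use summaries derive from per-drug days × events.

## Worked example

```python
from oudharmony import (GeneratorConfig, generate_clean_bundle,
                        inject_errors, run_pipeline,
                        compare_databases, score_recovery)

cfg = GeneratorConfig(n_subjects=20, seed=42)
bundles, truth = generate_clean_bundle(cfg)   # three raw dialect bundles
db = run_pipeline(bundles)                    # 23+3-table database
print(compare_databases(db, truth).summary())

corrupted, ledger = inject_errors(bundles, cfg)
rates = score_recovery(run_pipeline(corrupted), ledger)
for rule, r in sorted(rates.items()):
    print(f"{rule:22s} n={r['n']:3d}  recovered={r['rate']:.2f}")
```

prints

```
databases identical
date_offby1            n=  7  recovered=1.00
date_year_typo         n= 27  recovered=1.00
dose_other_drug        n=  3  recovered=1.00
drink_amount_missing   n=  6  recovered=1.00
drug_misspelling       n= 53  recovered=1.00
duplicate_uds          n=  5  recovered=1.00
eos_duplicate          n=  3  recovered=1.00
multi_drug_string      n=  8  recovered=1.00
```

`databases identical` is the end-to-end identity check: harmonizing a
clean bundle reproduces the generator's ground truth table for table.
Each recovery line reads, e.g., "27 year-typo'd dates were injected and
all 27 were repaired back to the ledgered true date."

The same workflow is available from the shell:

```
harmonize simulate --n 50 --seed 7 --out work/
harmonize run work/bundles --out work/harmonized
harmonize validate work/harmonized
harmonize check    work/harmonized
harmonize diff     work/harmonized work/ground_truth
harmonize summarize work/harmonized
```

Exit codes: 0 = clean, 1 = violations found, 2 = error.

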