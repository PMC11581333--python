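# Methods

## What the toolkit models

`oudharmony` treats harmonization of multi-study opioid-use-disorder
trial data as a deterministic, auditable transformation from three raw
"dialects" into one tidy relational database. A dialect
(`DialectSpec`) declares everything study-specific: the subject-ID
column spellings (seven exist across the three emulated studies), the
date format, per-column categorical code maps, the withdrawal and pain
instruments, the urine-panel composition, and the timeline-followback
(TLFB) layout. The pipeline itself contains no study-specific logic
beyond what the dialect declares, so a fourth study format is a new
descriptor, not new code.

The harmonized schema is fixed at 23 patient-level tables plus 3
metadata tables. Only a handful of table names are conventionally
established (demographics, tlfb, all_drugs, uds, uds_temp, withdrawal,
withdrawal_pre_post, meta_study_length); the remaining names were chosen
here to cover the harmonized survey domains one topic per table while
keeping the stated total of 23. The registry in `schema.py` is the
single source of truth; the codebook is emitted from it and
round-trips losslessly (`parse(emit(db)) == registry`).

Key coding conventions: `who` is a synthetic positive integer assigned
in deterministic first-seen order (projects in sorted order, then
screening-row order) because none of the seven raw alias schemes can
serve as a merged primary key; original IDs are retained in
`enrollment.raw_id`. `when` counts days from consent (day 0); study
weeks are separately anchored on the randomization date with
week = ⌊d/7⌋ + 1. Missing is first-class: distinct from 0 and from
"Refused", with missing-style category levels enumerated per variable.

## Crosswalks and cleaning rules

* **Withdrawal severity.** COWS (0–48) and SOWS (0–64) totals map onto
  one four-level ordinal by ordered rules: severe (COWS ≥ 25,
  SOWS ≥ 21), moderate (COWS ≥ 13, SOWS ≥ 11), mild (COWS ≥ 5,
  SOWS ≥ 1), else none. The instrument maxima are the published ranges
  (11 clinician-rated items; 16 self-rated items at 0–4 each);
  out-of-range scores are rejected rather than clamped, since a clamp
  would silently alter a severity category.
* **Pain.** The six SF-36 bodily-pain levels collapse onto the three
  EuroQoL-style levels (None → No Pain; Very Mild/Mild/Moderate → Very
  Mild to Moderate Pain; Severe/Very Severe → Severe Pain); the EuroQoL
  middle level maps to the middle harmonized level.
* **Education.** <12 years → Less than High School, =12 → High
  School/GED, >12 → More than High School. The direct-survey code 13
  ("high school graduate") is normalized to 12 years before binning,
  reconciling the two coding schemes; missing ASI years are backfilled
  from the direct survey where one exists.
* **Alcohol.** The drink-equivalence table uses 12 oz beer = 5 oz wine
  = 1.5 oz spirits = 1 standard drink; a half gallon (64 oz) of spirits
  is therefore 42.67 drinks, which is what makes the compound entry
  "6pk beer & 1/2 gal. rum" come out at 6 + 42.67 → 49. Totals round to
  the nearest integer at ≥ 10 drinks and to the nearest half drink
  below (round-half-up), reproducing both documented extremes (0.5 and
  49). Ambiguous "many"-type phrases code to 5 drinks. A missing amount
  on a drinking day is imputed with the subject's median known amount
  only when every known amount falls on one side of a 4-drink
  heavy/light line (the threshold is a module constant); mixed patterns
  stay missing with a flag.
* **Date repair** is a conservative cascade. Against an anchor (the
  recall-period end printed on a TLFB form): exact match → untouched; a
  whole-year shift that lands on the anchor → year repair; a one-day
  discrepancy → the survey date moves to the last TLFB day; anything
  else (e.g. the normal baseline backfill gap) is left alone. Against a
  context window ([consent − 60 d, last scheduled visit + 30 d]) plus an
  expected study week: candidates are year shifts of ±1–3, a day-digit
  transposition, and a month/day swap (attempted only for days ≤ 12); a
  repair is applied only when exactly one candidate fits, otherwise the
  record is flagged ambiguous or unrepairable and never guessed.
* **Duplicate urine panels** resolve in a fixed order: a justifying note
  keeps all rows; an entry timestamp that disagrees with the recorded
  date moves the record to the timestamp's date (after a timestamp
  repair the remaining same-date rows re-enter the cascade); an
  identical-result copy collapses to one row flagged end-of-study;
  contradictory rows with no context are all kept with an ambiguity
  flag. Ties are never broken randomly.
* **Doses.** Weekly log rows expand to their seven days; multiple
  same-day rows are summed (in-clinic plus take-home) — summation
  rather than max is a choice, logged per occurrence under
  `dose.same_day_sum` as normalization, not error repair. An isolated
  single-day record of the other study drug flanked by assigned-drug
  records is relabeled to the randomized assignment (`was_corrected` =
  1); runs of ≥ 2 such days fall outside the documented single-dose
  pattern and are flagged for review, not changed. Recorded zero doses
  stay in the table but are excluded from counts and averages.
  First-week dose summaries anchor on the first dose date rather than
  randomization, matching how induction differs from randomization;
  this is a keyword option in `summarize_treatment`'s week assignment.
* **Relapse.** A use week is a follow-up week with any qualifying
  positive urine screen; because the `uds` table already excludes the
  prescribed treatment drug, the qualifying set is simply the opioid
  categories (Heroin, Opioid, Methadone, Buprenorphine). "Four
  consecutive use weeks on or after Week 4" is read as the run's *first*
  week ≥ 4, so the earliest relapse run is weeks 4–7; the alternative
  end-anchored reading is available via `detect_relapse(...,
  anchor="end")`. Whether TLFB self-report can also set a use flag is a
  flag defaulting to urine-toxicology-only.

## The synthetic-data generator

The generator is the study-conditions definition, not a tuning knob. It
simulates per-subject latent state (demographics, weekly drug-use states
per category with heroin-dominant profiles in two dialects and a
prescription-opioid-dominant profile in the third, treatment arm and
dropout week, withdrawal scores, dose schedules) and then renders that
state twice: once into the three raw dialects, and once directly into
the ground-truth harmonized database. Raw values are generated first in
harmonized concept space and encoded through the dialect's code maps, so
ground truth is a deterministic function of the rendered values — the
identity test `pipeline(clean bundle) == truth` is exact, not
approximate.

Structural features emulated: a 28-day baseline TLFB block preceding
consent plus weekly follow-up blocks (dated long entries in one dialect,
wide `drug_d1…drug_d7` grids in the other two); per-dialect urine panels
(opiate assays at 300 and/or 2000 ng/mL, barbiturate and MDMA in one
dialect only, buprenorphine assays restricted to scheduled weeks in the
two-phase dialect); COWS vs SOWS; daily, weekly and same-day-split dose
logs plus every-4-weeks injections; two-phase re-randomization for a
configurable fraction; screened-but-never-randomized subjects (default
20%) who contribute baseline data only; and free-text alcohol strings
drawn from a template grammar whose standard-drink values are known by
construction.

Default sizes: 50 subjects per project and 24 follow-up weeks, matching
the six-month treatment horizon of the emulated designs and keeping the
full suite fast (the 150-subject end-to-end run takes a few seconds).
Error injection operates on the rendered bundles with per-rule
probabilities (year typos 3%, off-by-one survey dates 5%, day
transpositions 2%, duplicate panels 2%, end-of-study copies 10% of
subjects, misspellings 30% of free-text entries, compound strings 15%,
other-drug dose relabels 10% of dosed subjects, missing drink amounts
5%), each corruption recorded in a ledger with the true and corrupted
values so recovery is scored per rule, not in aggregate.

What the generator does *not* model — and therefore what passing tests
do not show about real data: marginal distributions are plausible but
not calibrated to any cohort; visit nonattendance is independent across
weeks; urine results are drawn per visit rather than from a
pharmacokinetic model; free-text variation is limited to the lexicon's
spellings plus the template grammar (the real free-text long tail is far
messier); and date errors are injected only in the patterns the repair
rules target, so recovery rates measure rule correctness, not expected
field performance.

## Numerical and implementation notes

* Quartiles use the median-of-halves rule (exclude the middle element at
  odd n), verified in tests against `statistics.median` on the sorted
  halves; percentages are reported to one decimal.
* Database comparison normalizes dtypes column-wise (numeric where every
  non-missing value parses, string otherwise), sorts by each table's
  declared key, and treats NaN = NaN; float cells compare with
  `np.isclose`.
* Exact duplicate raw rows are dropped with an audit entry; for this
  reason the generator renders same-day dose splits with unequal parts,
  since two identical rows are indistinguishable from an accidental
  duplicate.
* Re-harmonizing a harmonized database is covered as an I/O round-trip
  (write → read → compare is the identity) rather than by re-ingesting
  the harmonized CSVs through the dialect pipeline, which would require
  a synthetic "harmonized" dialect descriptor with no counterpart in
  real use.
* Validation (`validate_database`) checks referential integrity against
  enrollment, permitted values, declared uniqueness keys, and the
  tidy-shape rule (no day/week-suffixed column families); `strict`
  pipeline runs fail on any violation.

## Known limitations

Route and quantity of non-alcohol drug use are not harmonized (only
use/non-use per category per day). Full SF-36 domain scoring, QALY
derivation, and diagnostic-instrument internals are out of scope; only
the pain item and binary diagnosis flags are crosswalked. Equating COWS
and SOWS numerically beyond the four shared categories is not attempted.
Contradictory same-day urine results with no resolving context are kept
with a flag — consumers must decide how to treat them. The error-
recovery rates reported by `score_recovery` are conditional on the
generator's corruption patterns (see above).
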