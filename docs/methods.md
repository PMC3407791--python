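# Methods

This note documents the screening model, the evaluation procedures, the
synthetic-data generator, and the design decisions behind them, in enough
detail to reimplement the package from this file alone.

## The warehouse extract

A screening run reads a five-table flat-file extract: `patients.csv`,
`encounters.csv`, `diagnoses.csv`, `labs.csv`, `orders.csv`, with an
optional `manifest.json` carrying `extract_date`. CSV is comma-separated
UTF-8 with a header row and RFC 4180 quoting; all dates are strict ISO
8601 (`YYYY-MM-DD`) — a single unambiguous dialect, since date-entry
ambiguity is a classic failure mode of screening front-ends. ICD-9-CM
codes are normalized on load (dots stripped, upper-cased, validated
against the 3–5-digit / V / E grammar) so `428.1` and `4281` compare
equal; normalization is idempotent.

Validation on load: `patients.csv` is required (missing child tables are
empty); every child row's `patient_id` must resolve (violations name the
row and id); encounter `end_date >= start_date`; no record predates its
patient's birth. Clinical history rows may not post-date `extract_date`,
**except** `scheduled` encounters: future appointments are precisely what
pre-screening targets, so they legitimately lie after the snapshot date.
When no manifest is present, `extract_date` defaults to the latest date in
the extract.

## Criteria and checklists

Five criterion templates cover the checklists modeled here; each is
`include` or `exclude`:

| kind        | payload                                                            |
|-------------|--------------------------------------------------------------------|
| demographic | attribute (`age`, `sex`), comparator (LT/LE/GT/GE/EQ), value       |
| diagnosis   | ICD-9 code set, match mode, `primary_only`, optional window        |
| lab         | test code, lower/upper bound each with its own comparator, window  |
| encounter   | encounter type, optional clinic/physician sets, window             |
| medication  | drug code set, match mode, optional window                         |

Design choices worth stating:

* **Each lab bound carries an explicit comparator** (`GT` vs `GE`), because
  verbal phrasings ("more than" vs "at least") are demonstrably confused by
  users. Bounds must not be inverted; the parser rejects `lower >= upper`.
* **`IS_ANY_OF` is the default match mode.** `IS_EXACTLY` matches only when
  the code set is a single code equal to the record's; with several codes
  it can never match. That is a faithful model of the common authoring
  error (leaving "is exactly" selected for a multi-code criterion), and
  `validate_criterion` flags the combination rather than silently failing.
* **Exclusions are positive patterns with `polarity=exclude`**: "not
  currently pregnant" is authored as "pregnancy codes within the past 12
  months, exclude".
* **Temporal windows** are inclusive at both ends. `within_past_months: N`
  resolves to `[as_of − N months, as_of]` with calendar-month arithmetic
  clamped to end of month (one month before 2011-03-31 is 2011-02-28);
  `between_dates` is absolute with optional open ends.
* **Plausibility validation** (pure; returns issues, never raises): age
  comparands outside [0, 130] are rejected — expert reviews of the tool
  class this package models found fields happily accepting an age of 800 —
  and window dates outside [1900-01-01, reference + 5 years] are rejected,
  the 5-year headroom allowing forward-looking visit windows.

Checklists are JSON documents (`schema_version: 1`) with a `trial_id`, an
ordered non-empty `criteria` list with unique ids, a `visit_window`, and
optional clinic/physician filters. Parsing validates hard schema errors
with messages naming the field; `parse(serialize(x)) == x`. Four bundled
example checklists (two family-medicine diabetes trials: age ≥ 18, primary
type-2-diabetes codes, pregnancy-code exclusion within 12 months,
7 < HbA1c < 10; two heart-failure trials: age ≥ 21, hospitalization within
12 months, hypertensive or diastolic heart-failure codes) exercise every
template.

## Matching semantics

Per criterion, against one patient's bundle at a screening date `as_of`:

* **demographic** — age in completed years by birthday comparison (no
  365.25 approximation); sex compared case-insensitively with EQ. Never
  `UNKNOWN` (the extract always carries demographics).
* **diagnosis / medication / encounter** — *closed world*: any matching
  record inside the window ⇒ `MET`, none ⇒ `NOT_MET`, never `UNKNOWN`.
  `primary_only` restricts to primary diagnoses; encounter criteria filter
  on type and optional clinic/physician sets.
* **lab** — *open world*: no in-window result for the test code ⇒
  `UNKNOWN`; otherwise bounds are applied to the **most recent** in-window
  value (ties on date broken by load order, latest row wins). Screening
  asks about current state (HbA1c control), so older values do not vote.
* Records dated after `as_of` never contribute, window or not.
* `polarity=exclude` flips `MET` ↔ `NOT_MET`; `UNKNOWN` is a fixed point —
  absence of information is polarity-symmetric.

Checklist combination is Kleene conjunction: any `NOT_MET` ⇒ `INELIGIBLE`;
all `MET` ⇒ `ELIGIBLE`; otherwise `POSSIBLE`. The score is
`(# MET) / (# criteria)` — `UNKNOWN` contributes to `unknown_count`, not
the score. This is deliberately the simplest formula that supports the
stratification purpose (rank by how much is already satisfied, then by how
little is unresolved); it is isolated behind `evaluate_checklist` so a
different policy can replace it without touching criterion semantics.

`screen_population` evaluates only patients with a `scheduled` encounter
inside the checklist's visit window passing its clinic/physician filters —
a trial cannot approach a patient who is not coming in. Reports list
ELIGIBLE then POSSIBLE (INELIGIBLE omitted unless requested for evaluation
denominators), sorted by status, descending score, ascending unknown
count, then `patient_id`; with no wall-clock metadata in the output, two
runs on identical inputs are byte-identical. Every criterion result
carries the contributing records as evidence so reports can link back to
source data.

## Screening evaluation

`build_contingency(predicted, gold, population)` requires both sets to be
subsets of the population (violations list the offending ids) and counts
TP/FP/FN/TN; cells always sum to `|population|`. `compute_metrics` applies
the standard definitions (sensitivity, specificity, PPV, NPV, odds ratio)
and reports any zero-denominator metric as undefined (`None`) — a 0/0
silently rendered as 0 would fabricate a result. No continuity correction
by default; the Haldane–Anscombe +0.5 correction is available behind a
flag and labeled in the output. Whether `POSSIBLE` patients count as
predicted-positive is a study decision, exposed as `--positive-set
eligible|eligible+possible`.

## Heuristic-evaluation analysis

Per heuristic (Nielsen's ten principles), expert ratings on the 0–4 scale
are averaged (exact mean, rounded only for display) and classified:
**major** iff average ≥ 2.75 (the boundary is inclusive — an average of
exactly 2.75 is major), **cosmetic** iff average < 1.5 (strict), **minor**
otherwise. The thresholds partition [0, 4]. Checklist items are
independently assigned HCDIM categories (representational / task /
functional; the user-analysis category does not apply to instrument
items), and per-heuristic percentages are reported, summing to 100
whenever items exist and flagged empty otherwise.

## Terminology lookup

Vocabularies (ICD-9, lab, drug) are CSV: `code, preferred_name, synonyms`
(pipe-delimited). Matching is case-folded, whitespace-normalized substring
matching over names and synonyms, after expanding the query through
synonym equivalence classes (terms co-occurring in any entry's term set
are merged union-find style). The guaranteed contract is synonym closure:
two queries the vocabulary declares synonymous return identical result
sets — the repair for brand/generic search inconsistency. Ranking is
exact > prefix > substring with ties broken by code, so ordering is total
and deterministic. Substring matching (no tokenization or stemming) is the
smallest mechanism that honors the contract without a search-engine
dependency. The bundled vocabularies are illustrative fixtures, not
licensed terminologies.

## Synthetic populations and the oracle

The generator emulates the panel a family-medicine diabetes trial would
screen. Defaults (chosen once as a realistic mid-sized primary-care
panel): 200 patients; age ~ N(52, 19²) truncated to [5, 95]; type-2
diabetes prevalence 0.35 (an enriched diabetes clinic, and enough positives
for stable tests), heart failure 0.20, current pregnancy 0.04 among women
aged 15–50; HbA1c ~ N(8.0, 1.6²) truncated to [4, 15] % (≈60% of values
inside the 7–10 window); 30% of HbA1c values withheld from the extract;
85% of patients hold a scheduled visit in the 14-day window after the
2011-06-01 snapshot (an ICD-9-era date). Diabetic patients get a primary
diagnosis code; pregnant patients a pregnancy code inside the 12-month
window; 5% of non-pregnant women get a *stale* pregnancy code outside it
(must not trip the exclusion); heart-failure patients an inpatient stay
with a primary code; 30% get an unrelated noise diagnosis.

**Labels come from latent truth, not emitted records**: a withheld HbA1c
still has a true value, so the gold standard is complete (ELIGIBLE /
INELIGIBLE only) while the engine sees genuine UNKNOWNs — the same
asymmetry as manual chart review vs an automated query. Labels cover
exactly the patients holding a qualifying scheduled visit. Randomness is a
single `numpy` PCG64 stream (`default_rng(seed)`) drawn in a fixed
per-patient order, so a given config and seed reproduce the extract files
byte for byte.

What the generator does *not* emulate: correlation between conditions,
visit behavior conditional on illness, coding errors and granularity loss
(e.g. surrogate codes standing in for ejection fraction), measurement
noise, or free-text data. Passing tests therefore demonstrate the
engine's logical correctness against its stated semantics, not its
accuracy on real warehouse data, where code fidelity dominates.

`oracle_eligibility` is an independent brute-force evaluator: exhaustive
per-record loops, its own calendar-clamped month arithmetic and age
computation, sharing only the record dataclasses with the matcher. On
populations up to a few thousand it re-derives every verdict; the test
suite asserts record-for-record equivalence both on extracts enumerating
all achievable verdict vectors and on random synthetic populations.

## Numerical and degenerate-input choices

* Scores are exact fractions of small integers; CSV renders them to 4
  decimals, averages to 2 — rounding happens only at the display boundary.
* Empty extract ⇒ empty report (not an error); empty rating collections,
  empty queries and out-of-scale ratings raise input errors naming the
  value.
* Same-day duplicate labs: the last-loaded row wins, documented rather
  than arbitrary.
* Test problem sizes (500-patient recovery runs, 200-patient oracle
  comparisons, 12-patient enumerated extracts) were chosen as the smallest
  populations that exercise every code path with stable statistics; the
  whole suite runs in well under a minute.

## Known limitations

Only conjunctive checklists (no nested Boolean expressions); no free-text
criteria parsing; no NLP over reports (lab and code surrogates only); no
confidence intervals on screening metrics; the scoring policy is the
simple MET-fraction described above; closed-world coding means the
engine's real-world false-negative rate is bounded below by the
warehouse's coding fidelity, which no amount of matching logic can repair.
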