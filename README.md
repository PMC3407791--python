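# prescreen

Clinical trials recruit badly when every candidate must be found by manual
chart review. A data warehouse already holds the discrete data — diagnoses,
labs, encounters, medication orders — needed to pre-screen a clinic's
schedule and hand study coordinators a short, ranked list of patients worth
reviewing. `prescreen` is a toolkit for exactly that workflow, plus the
machinery to evaluate it: screening test characteristics against a gold
standard, and severity analysis of expert usability reviews of such tools.

It is aimed at clinical research informatics work: building and testing
eligibility phenotypes over flat-file warehouse extracts, without a live
EHR or SQL connection.

## The model

An eligibility checklist is a conjunction of templated criteria
(demographic, diagnosis, lab, encounter, medication; each `include` or
`exclude`). Criteria evaluate against a patient's records in **Kleene
three-valued logic** — `MET`, `NOT_MET`, `UNKNOWN`:

* **Closed world for coded events**: "no pregnancy ICD-9 code within the
  past 12 months" means *not pregnant*; absence of a billing code is
  evidence of absence, so diagnosis/medication/encounter criteria are never
  `UNKNOWN`.
* **Open world for labs**: no HbA1c on file resolves nothing, so
  `7 < HbA1c < 10` without an in-window result is `UNKNOWN`. With results,
  bounds apply to the most recent in-window value.

The checklist verdict is the Kleene conjunction: any `NOT_MET` ⇒
`INELIGIBLE`, all `MET` ⇒ `ELIGIBLE`, otherwise `POSSIBLE` (incomplete
data; follow up by hand). Candidates are scored by the fraction of
criteria definitively met and ranked deterministically.

Screening accuracy is summarized from the 2×2 table of predicted vs gold
eligibility: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV and
the odds ratio (TP·TN)/(FP·FN), with zero-denominator metrics reported as
undefined rather than 0. Usability reviews on Nielsen's ten heuristics
(ratings 0–4 per expert) are averaged per heuristic and classified:
average ≥ 2.75 **major**, < 1.5 **cosmetic**, **minor** between.

## Worked example

```python
import prescreen as ps

cfg = ps.SynthConfig(n_patients=200, seed=7)           # synthetic clinic panel
extract, gold = ps.generate_population(cfg)            # extract + latent truth
checklist = ps.fm_checklist(cfg.as_of, cfg.visit_days) # diabetes-trial criteria
report = ps.screen_population(extract, checklist, cfg.as_of)
print(report.n_screened, len(report.results))
```

Running `python examples/screen_trial_population.py` prints:

```
trial FM-SYNTH, as of 2011-06-01
screened 159 patients with a qualifying visit; 29 candidates
...
17 ELIGIBLE (all criteria met), 12 POSSIBLE (at least one UNKNOWN, none failed)
```

159 of 200 patients had a scheduled visit in the screening window; 17 meet
all four criteria outright and 12 are missing only their HbA1c, so a
coordinator would review those 29 charts instead of 200. The companion
`examples/evaluate_screening_accuracy.py` quantifies the effect of missing
labs: at 0% missingness the strict ELIGIBLE set recovers the latent truth
exactly (sensitivity = specificity = 1.0); at 30% missingness sensitivity
falls to 0.693 while specificity stays 1.0 — and counting POSSIBLE as
predicted-positive trades it back (sensitivity 1.0, specificity 0.946).

The other examples cover severity classification of a usability review
(`heuristic_severity.py`) and synonym-closed terminology search
(`code_lookup.py`).

## Command line

The same operations as a tool, for shell pipelines:

```bash
prescreen synth --n 200 --seed 7 --out data/           # extract + gold labels
prescreen run --criteria data/checklist.json --data data/ \
    --as-of 2011-06-01 --out report.csv
prescreen evaluate --predicted report.csv --gold gold.csv \
    --population population.csv --out metrics.json
prescreen validate --criteria checklist.json
prescreen lookup --vocabulary drug --query tylenol
prescreen heuristics --ratings ratings.csv --assignments hcdim.csv --out summary.csv
```

Exit codes: 0 success, 1 input/validation error (with a message naming the
field), 2 internal error. `docs/methods.md` documents all file formats and
the matching semantics in detail.

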