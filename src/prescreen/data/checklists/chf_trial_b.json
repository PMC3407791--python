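{
  "schema_version": 1,
  "trial_id": "CHF-B",
  "visit_window": {"kind": "between_dates", "start": "2011-06-01", "end": "2011-06-15"},
  "clinics": ["CARD-CLINIC-1"],
  "criteria": [
    {"id": "age", "kind": "demographic", "polarity": "include",
     "attribute": "age", "comparator": "GE", "value": 21},
    {"id": "hospitalization", "kind": "encounter", "polarity": "include",
     "encounter_type": "inpatient",
     "window": {"kind": "within_past_months", "months": 12}},
    {"id": "diastolic_hf", "kind": "diagnosis", "polarity": "include",
     "codes": ["428.30", "428.31", "428.32", "428.33"],
     "match_mode": "IS_ANY_OF"}
  ]
}
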