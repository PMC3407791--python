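{
  "schema_version": 1,
  "trial_id": "FM-B",
  "visit_window": {"kind": "between_dates", "start": "2011-06-01", "end": "2011-06-15"},
  "clinics": ["FM-CLINIC-1", "FM-CLINIC-2"],
  "criteria": [
    {"id": "age", "kind": "demographic", "polarity": "include",
     "attribute": "age", "comparator": "GE", "value": 18},
    {"id": "t2dm", "kind": "diagnosis", "polarity": "include",
     "codes": ["250.00", "250.02"],
     "match_mode": "IS_ANY_OF", "primary_only": true},
    {"id": "no_pregnancy", "kind": "diagnosis", "polarity": "exclude",
     "codes": ["V22.0", "V22.1", "V22.2"],
     "window": {"kind": "within_past_months", "months": 12}},
    {"id": "hba1c", "kind": "lab", "polarity": "include",
     "test_code": "HBA1C",
     "lower": {"value": 7, "comparator": "GE"},
     "upper": {"value": 10, "comparator": "LE"}}
  ]
}
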