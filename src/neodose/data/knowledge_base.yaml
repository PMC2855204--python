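# ILLUSTRATIVE knowledge base for testing the dose-checking machinery.
# The doses below are NOT clinical recommendations and must never be used
# for patient care.  Bands are closed intervals; within one drug+indication
# the bands partition patient space (validated at load).
drugs:
  - drug: ampicillin
    form: vial
    rules:
      - indication: any
        ga_weeks: [22, 44]
        pna_days: [0, 7]
        dose_mg_per_kg: 50
        interval_hours: 12
        tolerance: 0.10
      - indication: any
        ga_weeks: [22, 44]
        pna_days: [8, 365]
        dose_mg_per_kg: 50
        interval_hours: 8
        tolerance: 0.10
      - indication: meningitis
        ga_weeks: [22, 44]
        pna_days: [0, 7]
        dose_mg_per_kg: 100
        interval_hours: 8
        tolerance: 0.10
      - indication: meningitis
        ga_weeks: [22, 44]
        pna_days: [8, 365]
        dose_mg_per_kg: 75
        interval_hours: 6
        tolerance: 0.10
  - drug: gentamicin
    form: ampoule
    rules:
      - indication: any
        ga_weeks: [22, 34]
        pna_days: [0, 365]
        dose_mg_per_kg: 5
        interval_hours: 48
        tolerance: 0.10
      - indication: any
        ga_weeks: [35, 44]
        pna_days: [0, 365]
        gfr_at_least: 20
        dose_mg_per_kg: 4
        interval_hours: 24
        tolerance: 0.10
      - indication: any
        ga_weeks: [35, 44]
        pna_days: [0, 365]
        gfr_below: 20
        dose_mg_per_kg: 4
        interval_hours: 48
        tolerance: 0.10
  - drug: cefotaxime
    form: vial
    rules:
      - indication: any
        ga_weeks: [22, 44]
        pna_days: [0, 7]
        dose_mg_per_kg: 50
        interval_hours: 12
        tolerance: 0.10
      - indication: any
        ga_weeks: [22, 44]
        pna_days: [8, 365]
        dose_mg_per_kg: 50
        interval_hours: 8
        tolerance: 0.10
  - drug: phenobarbital
    form: ampoule
    rules:
      - indication: any
        ga_weeks: [22, 44]
        pna_days: [0, 365]
        dose_mg_per_kg: 4
        interval_hours: 24
        tolerance: 0.10
  - drug: phenytoin
    form: ampoule
    rules:
      - indication: any
        ga_weeks: [22, 44]
        pna_days: [0, 365]
        dose_mg_per_kg: 5
        interval_hours: 12
        tolerance: 0.10
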