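# Canonical parameter book: clinical event rates, utilities and US$ costs for
# stroke prophylaxis in non-valvular atrial fibrillation (65-year-old cohort).
# Every entry is a [base, low, high] triple; ranges are read as 95 % intervals.
# Rates are annual percentages, utilities are fractions, costs are US dollars.

model:
  start_age: 65
  horizon_cycles: 20
  cycle_length_years: 1.0
  discount_rate: 0.03
  wtp_threshold: 50000.0

# Share of neurological ischemic events that are TIAs rather than strokes (%).
tia_share: [28.00, 25.00, 33.00]

# Ischemic stroke severity splits (% of strokes), by antithrombotic class.
# The antiplatelet column sums to 99.9 %; it is renormalized on load.
severity_mixes:
  antiplatelet:
    fatal:      [17.90, 10.10, 17.90]
    mod_severe: [30.00, 30.00, 41.70]
    mild:       [41.00, 34.80, 41.00]
    none:       [11.00, 11.00, 13.30]
  anticoagulant:
    fatal:      [8.20, 5.50, 10.90]
    mod_severe: [40.20, 35.30, 45.10]
    mild:       [42.50, 37.60, 47.40]
    none:       [9.10, 6.20, 12.00]

utilities:
  mild_stroke:       [0.75, 0.75, 1.0]
  mod_severe_stroke: [0.39, 0.39, 1.0]
  mi:                [0.84, 0.84, 1.0]
  minor_hem:         [0.80, 0.50, 0.99]
  major_hem:         [0.80, 0.50, 0.99]

costs:
  inr_visit: [26.0, 10.0, 39.0]
  short_term:
    mod_severe_stroke: [14680.0, 6000.0, 25000.0]
    mild_stroke:       [9200.0, 3500.0, 15000.0]
    tia:               [7500.0, 3000.0, 12000.0]
    ich:               [38500.0, 15000.0, 60000.0]
  long_term:
    mod_severe_stroke: [5400.0, 2000.0, 8000.0]
    mild_stroke:       [2470.0, 1000.0, 4000.0]
    tia:               [5700.0, 2000.0, 9000.0]
    ich:               [7200.0, 3000.0, 12000.0]
  tee: [334.0, 167.0, 501.0]
  major_bleed: [4400.0, 1500.0, 6000.0]
  minor_bleed: [69.0, 34.5, 200.0]
  death_nonstroke: [10000.0, 5000.0, 20000.0]
  mi: [17000.0, 5000.0, 50000.0]
  hosp_stroke: [80964.0, 40482.0, 121446.0]
  hosp_pericardial: [73770.0, 36885.0, 110655.0]

strategies:
  aspirin:
    severity_class: antiplatelet
    rates:
      stroke:          [2.80, 2.80, 4.50]
      minor_hem:       [1.40, 1.27, 1.53]
      major_hem:       [1.00, 0.68, 1.32]
      ich:             [0.20, 0.19, 0.21]
      fatal_hem:       [0.20, 0.14, 0.26]
      mi:              [0.90, 0.77, 1.03]
      vascular_death:  [4.70, 4.48, 4.92]
      all_cause_death: [6.60, 5.53, 7.67]
    utility: [0.998, 0.994, 1.0]
    annual_drug_cost: [10.0, 5.0, 15.0]

  clopidogrel_aspirin:
    severity_class: antiplatelet
    rates:
      stroke:          [1.90, 1.69, 2.11]
      minor_hem:       [3.50, 2.58, 4.42]
      major_hem:       [1.50, 1.35, 1.65]
      ich:             [0.40, 0.24, 0.59]
      fatal_hem:       [0.30, 0.19, 0.51]
      mi:              [0.70, 0.53, 0.93]
      vascular_death:  [4.70, 4.18, 5.26]
      all_cause_death: [6.40, 5.87, 7.13]
    utility: [0.998, 0.994, 1.0]
    annual_drug_cost: [1857.0, 365.0, 2785.5]

  warfarin:
    severity_class: anticoagulant
    rates:
      stroke:          [1.21, 1.05, 1.42]
      minor_hem:       [18.63, 11.40, 25.80]
      major_hem:       [3.32, 3.09, 3.57]
      ich:             [0.75, 0.70, 0.80]
      fatal_hem:       [0.90, 0.50, 1.80]
      mi:              [0.78, 0.61, 1.12]
      vascular_death:  [2.10, 1.71, 2.69]
      all_cause_death: [2.89, 0.50, 4.13]
      hospitalization: [20.80, 15.50, 26.10]
    utility: [0.987, 0.953, 1.0]
    annual_drug_cost: [180.0, 60.0, 270.0]
    inr_monitoring: true

  dabigatran_110:
    severity_class: anticoagulant
    rates:
      stroke:          [1.34, 1.31, 1.55]
      minor_hem:       [13.20, 12.60, 13.80]
      major_hem:       [2.87, 2.50, 3.32]
      ich:             [0.23, 0.14, 0.32]
      fatal_hem:       [1.22, 1.08, 1.36]
      mi:              [0.82, 0.61, 1.12]
      vascular_death:  [2.43, 2.23, 2.63]
      all_cause_death: [3.75, 3.51, 3.99]
      hospitalization: [19.40, 13.49, 25.32]
    utility: [0.994, 0.975, 1.0]
    annual_drug_cost: [3240.0, 2500.0, 4860.0]

  dabigatran_150:
    severity_class: anticoagulant
    rates:
      stroke:          [0.92, 0.75, 1.09]
      minor_hem:       [14.80, 14.20, 15.50]
      major_hem:       [3.32, 2.89, 3.82]
      ich:             [0.30, 0.20, 0.40]
      fatal_hem:       [1.45, 1.33, 1.56]
      mi:              [0.81, 0.60, 1.09]
      vascular_death:  [2.28, 2.03, 2.53]
      all_cause_death: [3.64, 3.28, 4.00]
      hospitalization: [20.20, 19.94, 20.46]
    utility: [0.994, 0.975, 1.0]
    annual_drug_cost: [3240.0, 2500.0, 4860.0]

  apixaban:
    severity_class: anticoagulant
    rates:
      stroke:          [0.97, 0.78, 1.19]
      minor_hem:       [18.10, 17.54, 19.35]
      major_hem:       [2.13, 1.85, 2.47]
      ich:             [0.33, 0.24, 0.46]
      fatal_hem:       [0.37, 0.30, 0.42]
      mi:              [0.53, 0.40, 0.71]
      vascular_death:  [1.80, 1.54, 2.10]
      all_cause_death: [3.52, 3.15, 3.90]
      hospitalization: [20.80, 15.50, 26.10]
    utility: [0.994, 0.975, 1.0]
    annual_drug_cost: [3920.1, 1960.1, 5880.2]

  rivaroxaban:
    severity_class: anticoagulant
    rates:
      stroke:          [1.34, 1.07, 1.66]
      minor_hem:       [11.80, 10.94, 12.88]
      major_hem:       [3.60, 3.06, 4.08]
      ich:             [0.50, 0.33, 0.65]
      fatal_hem:       [0.20, 0.16, 0.40]
      mi:              [0.91, 0.71, 1.19]
      all_cause_death: [4.50, 4.01, 4.99]
      hospitalization: [20.80, 15.50, 26.10]
    utility: [0.994, 0.975, 1.0]
    annual_drug_cost: [2660.9, 1330.4, 3991.3]

  laao:
    severity_class: anticoagulant
    # Rates from the second year onward (lifelong aspirin after occlusion).
    rates:
      stroke:          [0.84, 0.40, 1.10]
      minor_hem:       [1.40, 1.27, 1.53]
      major_hem:       [1.00, 0.68, 1.32]
      ich:             [0.20, 0.19, 0.21]
      fatal_hem:       [0.20, 0.14, 0.26]
      mi:              [0.90, 0.77, 1.03]
      all_cause_death: [3.20, 1.56, 4.84]
      hospitalization: [1.08, 0.00, 5.00]
    # First post-implant year: 45 days warfarin, 180 days clopidogrel+aspirin,
    # then aspirin (pro-rata bleeding/MI rates as printed).
    first_year_rates:
      stroke:          [0.84, 0.40, 1.10]
      minor_hem:       [4.28, 3.70, 4.86]
      major_hem:       [1.54, 1.30, 1.77]
      ich:             [0.37, 0.27, 0.47]
      fatal_hem:       [0.45, 0.38, 0.51]
      mi:              [0.76, 0.57, 1.00]
      all_cause_death: [3.20, 1.56, 4.84]
    utility: [0.998, 0.994, 1.0]
    annual_drug_cost: [0.0, 0.0, 0.0]   # regimen drug cost is built pro-rata
    laao_extras:
      implant_success: [0.868, 0.8342, 0.9018]     # fraction
      pericardial_effusion: [2.07, 1.50, 2.40]     # % within 7 days
      total_cost: [22500.0, 20384.0, 24614.0]      # procedure + device, US$
      warfarin_days: 45
      dual_days: 180
      tee_exams: 2
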