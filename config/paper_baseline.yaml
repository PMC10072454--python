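# Baseline run configuration: the five published tax scenarios with their
# externally estimated average retail price increases, the aggregate market
# calibrated from the scenario-1 outcome, and all default parameters.
scenarios:
  - {id: scenario1, tax_type: ad_valorem, rate: 0.10, avg_price_increase: 0.05}
  - {id: scenario2, tax_type: specific_volume, rate: 3500, avg_price_increase: 0.11}
  - {id: scenario3, tax_type: specific_sugar, rate: 60, avg_price_increase: 0.19}
  - {id: scenario4, tax_type: specific_volume, rate: 7000, avg_price_increase: 0.20}
  - {id: scenario5, tax_type: ad_valorem, rate: 0.40, avg_price_increase: 0.20}

elasticity: -1.14

calibration_inputs:
  printed_decrease_s1: 171.3     # million litres/year at a 5% price rise
  price_increase_s1: 0.05
  per_capita_decrease_s1: 2.6    # litres/person/year
  energy_decrease_s1: 13.7       # kJ/person/day (fixes mean sugar density)

cohort_spec:
  n: 3856                        # mirrors the source survey sample size
  seed: 0
  sex_split: 0.5
  target_mean_bmi: 21.96

energy_weight:
  adult_kj_per_kg: {male: 93.0, female: 72.3}
  child25_kj_per_kg: {male: 216.0, female: 204.0}
  hall_intercept: {male: 68.0, female: 62.0}
  hall_slope: {male: 2.5, female: 2.2}
  kcal_to_kj: 4.184
  maturity_fraction: 1.0         # full equilibrium change at the 3-year horizon

diabetes:
  rrr_per_2_bmi: 0.27
  rrr_ci: [0.23, 0.30]
  baseline_prevalence: 0.041
  adult_population: 67.0e+6
  complication_share: 0.5
  cost_with_complications: 10.5e+6      # VND/case, synthetic placeholder
  cost_without_complications: 4.812e+6  # VND/case, synthetic placeholder
  vnd_per_usd: 22370.0
  dose_response: linear

mc:
  iterations: 10000
  seed: 0
  model: model1
  conversion_mean: {male: 93.0, female: 72.3}
  conversion_cv: 0.05
  rrr_mean: 0.27
  rrr_ci: [0.23, 0.30]
  rrr_fit: ci

sa_elasticities: [-1.14, -1.0, -0.8]
outputs: outputs
seed: 0
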