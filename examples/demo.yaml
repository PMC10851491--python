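sim:
  seed: 42
  years: [2001, 2002]
  n_cases: 8000
plan:
  thresholds: [0.9]
  heat_percentiles: [95]
  pm_exposures: [pm25, pm25_ma_5]
  heat_exposures: [any_heat, wave_day_1]
  subgroups: [all]
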