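# Example cohort for `comorbits run-all --config examples/config.yaml --out out/`
simulation:
  n_exposed: 2000
  n_control_pool: 2500
  seed: 11
  index_year_range: [2008, 2017]
  secular_slope: 1.0           # % per year, both groups
  conditions:
    - condition_id: attention
      baseline_hazard: 0.0008  # monthly onset probability pre-index
      index_spike: 0.03        # extra onset probability in month 0, exposed only
      post_slope_delta: 0.0008 # hazard step after index, exposed only
    - condition_id: pain
      baseline_hazard: 0.006
      index_spike: 0.08
      post_slope_delta: 0.0005
    - condition_id: stroke
      baseline_hazard: 0.0002
      index_spike: 0.005
      post_slope_delta: 0.0001
    - condition_id: cad
      baseline_hazard: 0.002   # no exposure effects: a negative control
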