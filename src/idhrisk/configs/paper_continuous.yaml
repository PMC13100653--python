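# Continuous concurrent-association scenario: hazard term on delta-RBV
# (log odds-ratio 0.0516 = ln 1.053 per 1-point increase in 100 - RBV).
# Intercept produced by calibrate_intercept targeting 29.7% session incidence.
cohort: {}
effect:
  mode: continuous
  intercept: -4.4248
  sigma_b: 1.67
  terms:
    delta_rbv: 0.051643
  centers: {}
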