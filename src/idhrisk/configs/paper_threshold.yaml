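# Below-dynamic-threshold scenario: hazard indicator term (log OR 0.8629 =
# ln 2.37) on RBV falling below the generator threshold tau(t), which runs
# linearly from 100% at t=0 to 88% at 240 min.
# Intercept produced by calibrate_intercept targeting 29.7% session incidence.
cohort: {}
effect:
  mode: threshold
  intercept: -4.4189
  sigma_b: 1.67
  terms:
    below_threshold: 0.862890
  centers: {}
  threshold_curve:
    t: [0, 240]
    rbv: [100.0, 88.0]
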