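# Multivariable predictive scenario: the hazard at each vitals time uses the
# covariates observed at the previous vitals time (below-threshold indicator,
# dRBV/dt in %/min, SBP mmHg, delta-SBP mmHg, HR bpm), with published
# odds ratios 1.68 / 0.26 / 0.94 / 1.02 / 1.02 as the injected log-ORs.
# SBP and HR are centered at their typical levels so the intercept stays in
# a calibratable range.
# Intercept produced by calibrate_intercept targeting 29.7% session incidence.
cohort: {}
effect:
  mode: multivariable
  intercept: -4.7764
  sigma_b: 1.67
  terms:
    below_threshold: 0.518794
    drbv_dt: -1.347074
    sbp: -0.061875
    delta_sbp: 0.019803
    hr: 0.019803
  centers:
    sbp: 128.8
    hr: 74.0
  threshold_curve:
    t: [0, 240]
    rbv: [100.0, 88.0]
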