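# Trajectory-archetype scenario: session-level high-risk membership
# (steep-decline or intermediate archetype vs plateau) carries log OR
# 0.9478 = ln 2.58.  Low trajectory noise keeps archetypes recoverable by
# blind DTW clustering.
# Intercept produced by calibrate_intercept targeting 29.7% session incidence.
cohort:
  trajectory_noise_sd: 0.3
effect:
  mode: archetype
  intercept: -4.4365
  sigma_b: 1.67
  terms:
    high_risk: 0.947789
  centers: {}
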