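# Methods

`idhrisk` implements an analysis pipeline for intradialytic hypotension (IDH)
risk from continuous relative blood volume (RBV) monitoring, together with a
synthetic-cohort generator that makes every stage testable by parameter
recovery. This note records the models, the generator, the numerical choices,
and the limits of what the tests demonstrate.

## Core definitions

**RBV.** The blood volume monitor reports hematocrit every minute; RBV is
`100 · Ht(0) / Ht(t)` (%), starting at 100% and falling as ultrafiltration
concentrates the blood. The baseline `Ht(0)` defaults to the mean of minutes
0–2 (robust to sensor settling); a single-first-value baseline is available
and makes `RBV(0) = 100` exact. With the averaged baseline `RBV(0)` may
deviate from 100 by the early-minute noise (validation allows 1%).

**IDH.** A vitals entry is flagged when systolic pressure is below 90 mmHg
*and* at least 20 mmHg below the session's first recorded systolic pressure.
The absolute-nadir component follows the outcome-oriented definition
validated for mortality risk; the relative component uses the pre-dialysis
reading because it cannot be influenced by intradialytic interventions.

**Prediction rows.** Each vitals entry yields one modelling row with
features: RBV (%), ΔRBV = 100 − RBV, dRBV/dt (trailing 10-min least-squares
slope, %/min; undefined before t = 10, such rows are dropped), SBP, ΔSBP =
baseline SBP − current SBP, heart rate, and optionally a below-threshold
indicator. Labels are either *concurrent* (the entry's own flag) or
*horizon* (1 iff any flagged entry lies in `(t+10, t+60]`; the entry at `t`
never labels itself). Horizon windows are truncated at the session end;
rows whose truncated window is empty, and rows where IDH is already ongoing
at `t` (configurable), are dropped.

## Mixed-effects logistic model

The central model is

  y_ij | b_i ~ Bernoulli( expit( x_ij' β + b_i ) ),  b_i ~ N(0, σ_b²),

with one random intercept per patient. `MixedLogit.fit()` maximises the
marginal likelihood; each patient's integral over b_i uses adaptive
Gauss–Hermite quadrature (default 21 nodes) centred and scaled at the
per-patient posterior mode, found by damped (backtracking) Newton — the
log-posterior is concave in b but an undamped step can overshoot where the
logistic curvature vanishes. One node reduces to the Laplace approximation;
σ_b below 1e-6 reduces to plain logistic regression. Optimisation is
L-BFGS-B over (β, σ_b) with σ_b ≥ 0; standard errors come from the inverse
observed information (numerical Hessian); Wald intervals are reported as
odds ratios. Estimates at 21 vs 41 nodes agree to <1e-4 on the test
fixtures, and the implementation matches lme4's `glmer` (nAGQ = 25) to ~1e-3
on a shared fixture.

Prediction adds the posterior-mode intercept for patients seen during
fitting when random effects are requested; unseen patients always receive
fixed effects only — the reason patient-wise validation is systematically
harder than session-wise validation.

## Trajectory clustering and the dynamic threshold

Sessions are clustered on their raw per-minute RBV series with classic DTW
(absolute-difference local cost, unit steps, optional Sakoe–Chiba band; no
z-normalisation, since the level carries the signal) and PAM-style k-medoids
(k = 3 by default, multiple restarts, greedy best swap; average-linkage
hierarchical clustering is a config alternative). k-medoids is used because
DTW admits no well-defined barycentre at this simplicity level, and it needs
only the precomputed distance matrix. The cluster with the lowest
session-level IDH incidence becomes the low-risk reference; all others merge
into the high-risk group (ties broken toward the larger cluster).

The time-dependent threshold τ(t) is derived on a 5-min grid: at each time,
RBV values of sessions still running are pooled by risk group and the cutoff
maximising Youden's J (classifying below-cutoff as high-risk) is recorded;
candidate cutoffs are midpoints between adjacent distinct pooled values,
with the lowest maximizing gap's midpoint on ties and a J = 0 floor when the
groups are inverted. The raw cutoffs are LOESS-smoothed (local linear,
tricube weights, span 0.3 by default) and a pointwise percentile bootstrap
(resampling sessions within risk group; B = 1000 reported, 200 in tests)
gives the 95% band. The crossing indicator is strict: `RBV < τ(t)` with
linear interpolation between grid points and nearest-value extrapolation.
When the threshold feeds a predictive model it should be derived on training
sessions only; the library leaves the split to the caller and the CLI wires
it accordingly.

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes, not
cardiovascular mechanism (no baroreflex, cardiac output or temperature
physiology). Defaults emulate the study design: 56 patients × 9 sessions of
240 min, vitals every 30 min, pre-dialysis SBP 128.8 ± 24.4 mmHg, hematocrit
baseline per patient ~N(34, 3²)% (≈3× a hemoglobin of 11.5 g/dl), and a 9%
session-dropout option that mimics 459 usable of 504 scheduled sessions.

**Trajectories.** Per-minute RBV follows
`rbv(t+1) = rbv(t) − u + k_r (100 − rbv(t)) + ε_t`, a first-order
ultrafiltration/refilling balance with fixed point `100 − u/k_r`. Three
archetypes (mix 0.4/0.2/0.4) set the drive u: steep 0.30, plateau 0.08,
intermediate 0.18 %/min with k_r = 0.01/min and step noise 0.3%, spreading
final RBV over roughly 72–93% so that the plateau (low-risk) cluster ends
high and the steep cluster low, as the real trajectory clusters do. These
rates are not published anywhere; they were chosen once to make the final-RBV
spread qualitatively match the reported cluster contrast and are not tuned
to reproduce any printed value.

**Events and vitals.** At each vitals time a logistic hazard
`expit(β0 + Σ β_f (x_f − c_f) + b_i)` draws the IDH flag; SBP is then drawn
from the truncated-normal region *consistent with the flag* under the
labeling rule (flagged: below `min(90, baseline − 20)`; unflagged: above),
so relabelling the simulated vitals reproduces the simulated events exactly.
SBP is autocorrelated within session (innovation SD 7 mmHg around a −1.5
mmHg/interval drift, matching the pre/post-dialysis SBP difference); heart
rate is a small random walk. Four effect modes mirror the analyses:
concurrent ΔRBV, concurrent below-τ indicator (τ_gen runs linearly from
100% to 88% at 240 min — 88% matching the terminal value reported for
empirically derived RBV thresholds), session-level high-risk archetype, and
a multivariable mode whose hazard at time s uses the covariates observed at
s − 30 (below-τ, dRBV/dt, SBP, ΔSBP, HR; SBP and HR centred at 128.8 and
74). The one-interval lag is what keeps the label-consistent SBP draw
acyclic: SBP at s cannot simultaneously be drawn from the flag-consistent
region and be a free covariate of that same flag.

**Calibration.** `calibrate_intercept` bisects β0 so the session-level IDH
incidence hits a target (29.7% by default). Because a single 56-patient
cohort's incidence is dominated by the luck of its patient-intercept draws
(SD ≈ 5 percentage points), the calibration objective integrates the random
intercept out by Gauss–Hermite quadrature and the event draws out via the
no-event product along ≥2000 simulated covariate paths under common random
numbers; the objective is then smooth and strictly increasing in β0 and
agrees with brute-force simulation to <0.01. The packaged configurations
(`paper_continuous`, `paper_threshold`, `paper_archetype`,
`paper_multivariable`) carry intercepts produced this way together with the
published effect sizes as injected log-odds-ratios and σ_b = 1.67.

**Determinism.** One `SeedSequence` per cohort is spawned hierarchically
patient → session (PCG64 streams); the same seed yields byte-identical CSVs.

## Known biases of the horizon construction

Two structural effects, quantified at 400-patient scale, are worth knowing:

- *Errors-in-variables attenuation (multivariable mode).* A horizon row at t
  is labelled by events at t+30 and t+60, but the t+60 event's hazard used
  the covariates at t+30. Fitted coefficients are therefore attenuated by
  the covariates' 30-min autocorrelation — at most ~0.6 fitted SE at study
  scale, largest for ΔSBP.
- *Random-intercept inflation.* Consecutive horizon windows overlap (one
  event labels two rows), adding within-patient label correlation beyond the
  injected intercept; the horizon-mode σ̂_b centres near 1.9 when 1.67 is
  injected (a non-overlapping row subsample recovers ~1.64, the concurrent
  fit ~1.60). Recovery tests use the ±0.35 band that reflects both this and
  the sampling spread of a variance component estimated from 56 groups.

## Evaluation

Splits are patient-wise (random patient partition; fixed-effects-only
predictions on the held-out patients) or session-wise (each patient's
earliest ⌈0.7 n_i⌉ sessions train, later sessions test; patient intercepts
usable). AUC is the tie-corrected concordance probability; the operating
point maximises Youden's J over observed scores and reports sensitivity,
specificity, NPV and PPV from the resulting table. The descriptive suite
bins concurrent RBV at 5%-wide left-closed categories (≥95 reference) with
two-sided Fisher exact tests, compares RBV between flagged and unflagged
entries by tie-corrected Wilcoxon rank-sum, and tests cumulative IDH between
risk groups at each 30-min mark by Fisher exact test.

## What passing tests do and do not show

The generator draws events from exactly the model family that is later
fitted, so recovery tests validate the estimation and pipeline machinery —
they cannot validate the clinical model itself. Real monitoring data differ
in ways the generator deliberately omits: access recirculation artifacts in
hematocrit, interventions (ultrafiltration reduction, saline) that truncate
incipient events and feed back into the trajectory, missing and irregular
vitals, non-Gaussian patient heterogeneity, and within-patient drift across
sessions. Reported problem sizes (56 × 9 cohorts; 5–30 replicate cohorts
per recovered quantity; B = 200 bootstrap replicates in tests) were chosen
to keep each recovered quantity's Monte-Carlo error well inside the
acceptance band it is judged against.
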