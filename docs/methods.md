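# Methods

## Problem setting

Acute stroke trials measure functional outcome on the modified Rankin
Scale (mRS): an ordinal scale with 0 = no symptoms through 5 = severe
disability and 6 = death. The scale is typically collected repeatedly
(around days 7–10, 90, 180 and 360 after randomization) but analyzed once,
at 90 days, and often after collapsing it to a binary "favorable outcome"
(mRS ≤ 1). This package implements (a) a continuous-time multistate Markov
model (MSMM) that uses the full ordinal scale at every visit, (b) a
PCA-based reconstruction of the unobservable baseline mRS, and (c) the
battery of conventional single-endpoint analyses, so the approaches can be
compared on the same data — real or simulated.

## The multistate Markov model

The disease process is a continuous-time Markov chain on the mRS states.
Its generator Q holds transition intensities q_rs ≥ 0 (instantaneous risk
of moving from state r to state s); rows sum to zero, and the death row is
zero (absorbing). Because the underlying process is continuous, direct
transitions are allowed only between adjacent disability states; the
*general* structure also allows death from every transient state, and the
*reduced* structure (the default) allows death only from states 4 and 5 —
the reduction supported when intensities to death from mild states are
estimated near zero (`reduce_structure` automates this pinning workflow).

Covariates act proportionally on intensities:
q_rs(x) = q_rs⁰ · exp(Σ_c β_rs,c x_c), so exp(β) is a per-transition hazard
ratio. Intensities may be piecewise-constant across epochs split at
breakpoints (default: none; the with-baseline battery entry uses a single
breakpoint at 90 days separating acute from chronic dynamics — the
breakpoint is a configuration choice, not an estimate).

Panel data (states seen only at visit times t_j) contribute likelihood
terms P_{y_j,y_{j+1}}(t_{j+1} − t_j) with P(t) = expm(Qt); an interval that
crosses a breakpoint uses the ordered product of epoch-wise matrix
exponentials (exact, not an approximation). Death dates are usually known
exactly in trials, so by default (`death_mode="exact"`) a transition into
death contributes the absorption density Σ_k P_{y_j,k}(dt)·q_{k,death}
instead of a panel term; `death_mode="panel"` is available. A separate
`observation="exact"` mode implements the complete-data likelihood for
processes whose every transition time is recorded (its MLE is the
count/exposure closed form, which the tests exploit as an oracle).

### Numerics

* Likelihood evaluation diagonalizes Q once per (covariate pattern, epoch)
  and evaluates expm(Q·dt) for all interval lengths at once via
  U·diag(exp(λ·dt))·U⁻¹; intervals are pre-grouped at model construction.
  If the eigenvector matrix is ill-conditioned (cond > 1e8) the code falls
  back to scipy's expm per interval. The public
  `transition_probability` always uses scipy's expm.
* Optimization is bounded quasi-Newton (L-BFGS-B) on (log q, β) with
  gradient tolerance 1e-6 and `ftol` 1e-12; log intensities are floored at
  −16 instead of failing, mirroring the "set small intensities to zero"
  workflow while keeping the likelihood smooth.
* Starting values are crude count/exposure rates, with multi-step panel
  moves decomposed along the shortest adjacent path and exposure split
  equally along it.
* Standard errors come from the inverse finite-difference observed
  information; parameters on the boundary are excluded (their CIs are
  reported missing).
* Boundary detection: a transition whose estimated log intensity is very
  small is flagged as "effectively zero" when pushing it to the floor
  changes the log-likelihood by less than 0.02 — the gradient with respect
  to a vanishing intensity itself vanishes, so the optimizer never
  literally reaches the floor.
* Ties in observation time within a subject are a validation error, never
  silently merged.

### Inference

Nested models are compared by likelihood-ratio tests. The global treatment
test places a treatment coefficient on every free transition (12 for the
reduced structure) and compares against the all-zero model by a 12-df LRT;
the null fit warm-starts the alternative.

**Known limitation (measured, not hypothesized):** in sparse panels —
transitions with a handful of observed moves, as in NINDS-like worlds with
slow chronic dynamics — the 12-df chi-square reference is anticonservative,
because arm-specific rate estimates for rare transitions sit near the
boundary. The calibration test therefore runs in an information-dense
world (events observed on all 12 transitions); per-transition hazard-ratio
CIs are well calibrated much earlier (coverage test at n = 500/arm on a
3-state chain). Interpret small global-test p-values cautiously when some
transitions are rarely observed.

## Predicted baseline mRS

The mRS cannot be assessed at stroke onset, yet most recovery happens
early. The baseline module reconstructs a latent baseline state from
severity covariates (NIHSS items and total, age, glucose,
onset-to-randomization time, early CT score):

1. correlation-matrix PCA (covariates are on wildly different scales) on
   complete cases; constant variables dropped; components retained by the
   Kaiser rule (eigenvalue > 1; cumulative-variance ≥ 80% available); signs
   fixed so each retained component correlates positively with the NIHSS
   total, making the composite a severity score;
2. the composite is the eigenvalue-weighted sum of retained component
   scores, standardized over the fitting sample;
3. subjects are ranked by composite and partitioned by the cumulative
   quantiles of a configurable target distribution over states 0–5 (worst
   scores → state 5; ties broken by stable subject-id order). The default
   target (mass 0.10/0.20/0.35/0.35 on states 2–5) reflects that
   trial-eligible acute strokes are rarely mild at onset.

The exact published score-to-state mapping is not recoverable from the
literature we re-implement; the rank/quantile mapping is our
reconstruction and every choice in it is configuration. Subjects with
missing covariates receive no baseline and fall back to the no-baseline
path with a log entry. The assignment is attached to the panel as a
time-0 pseudo-observation.

**What the attachment does and does not buy (measured).** The panel
likelihood conditions on each subject's first observation, so without a
baseline all treatment information in the 0 → first-visit window is
discarded; attaching a baseline restores that interval. With a first
visit at 7–10 days this is a second-order gain: in our synthetic worlds
(constant or acute-phase-only treatment effects, 24 replicates each) the
with-baseline global test was *not* systematically more powerful than the
no-baseline test — even when the true initial state was attached instead
of the noisy PCA assignment, and distinctly less powerful when the
with-baseline model also switched to piecewise intensities (the extra
parameters cost more than the extra interval earns at trial scale). The
single-dataset improvement reported in the re-analysis literature
(p 0.053 → 0.0018) therefore should not be read as a general property.
More seriously, attaching the *predicted* baseline as if it were an
observed state is measurably anticonservative: the assignment
misclassifies the latent state (Spearman ≈ 0.6–0.7 against truth under
the default covariate loadings), the Markov model explains those
time-0 errors with spurious extreme rates, and the misspecified 12-df
global LRT then rejects a true null far above the nominal level (11/30
null replicates at α = 0.05 in our measurement, versus 2/30 when the
error-free latent state is attached). The validity test therefore uses
the oracle baseline — the correctly-specified guarantee — and with-
baseline p-values from the battery should be interpreted with this
caveat; it also colors the published with-baseline re-analysis results.
A hidden-Markov treatment of baseline misclassification would address
this and is explicitly out of scope here.

## Synthetic trials

The generator states a world: continuous-time Markov trajectories per
subject (competing exponential clocks; epoch changes honored by clock
truncation, valid by memorylessness), treatment acting multiplicatively on
chosen intensities, visits at jittered nominal days (uniform jitter — the
magnitude, not the law, is what the emulated design states), death
recorded at its exact simulated day, and baseline covariates tied to the
initial state through a shared latent severity factor standardized by the
*theoretical* initial-distribution moments. Each subject draws from an
independent substream keyed by (seed, arm, index), so enlarging a trial
never perturbs already-generated subjects.

Defaults mimic NINDS scale: 310 per arm; visits 8.5/90/180/360 with
jitter 1.5/10/10/10 days; an acute epoch (first 90 days: recovery 0.020,
worsening 0.006, death 0.004 from state 4 and 0.012 from state 5, per
day) and a chronic epoch at 0.15× those rates; initial severity massed on
states 3–5. The covariate marginals and severity loadings (e.g. NIHSS
total loading 0.80, age 0.25, early CT score −0.35) are plausible stand-ins
declared in configuration — the emulated trial's covariate-generating
process is unknown, so none of these values is a claim about real data.
What the generator does not emulate: informative missingness (dropout is
MCAR), semi-Markov dynamics, measurement error in the mRS. A green test
against this world establishes correctness of the machinery under the
model's own assumptions, not robustness to their violation.

## Comparator battery

Every analysis returns the same result contract (method, outcome
definition, labelled statistics with 95% Wald CIs, p-value) and the table
is written as CSV with fixed columns. Conventions:

* fixed dichotomy: favorable = mRS ≤ 1; logistic regression OR.
* linear regression on the raw scale reports control − treatment
  (positive = benefit); on utilities, treatment − control. Direction is in
  the statistic label because the field's tables rarely print it.
* utility-weighted mRS: weights are configuration; the shipped placeholder
  is a synthetic linear ramp (1, 5/6, …, 0), *not* the published weights.
* CMH shift test: stratified row-mean-scores-differ statistic, 1 df,
  integer scores 0–6 by default with modified-ridit scores available; no
  effect size (the test has none). On the packaged NINDS 90-day counts the
  ridit convention reproduces the published p = 0.0017 (integer scores
  give 0.0026), suggesting the published analysis used ridit scores; the
  integer default follows the declared interface and the finding is
  documented rather than silently switched.
* POM via statsmodels' OrderedModel; the OR is oriented so OR > 1 means
  better (lower) outcomes under treatment.
* restricted PPOM: cumulative-logit ML with arm log-odds at cut j equal to
  β0 + γ·j (a linear deviation from proportional odds), implemented here
  (no installed package exposes it); reports all six cut-specific ORs with
  delta-method CIs and a 2-df LRT. γ = 0 reproduces the POM exactly —
  asserted against the independent OrderedModel fit.
* ACAT: adjacent-categories logit with category-specific effects, fitted
  as the equivalent multinomial logit; ORs compare the lower to the higher
  category of each adjacent pair (OR > 1 favors the better outcome);
  global (K−1)-df LRT.
* sliding dichotomy: success is mRS 0 / ≤1 / ≤2 for NIHSS ≤7 / 8–14 / >14.
  The published bands omit NIHSS = 7; it is folded into the mild band for
  contiguity, and the edges are configurable. No NIHSS adjuster (severity
  is already encoded).
* GEE: marginal logistic model across visits, independence working
  correlation by default (exchangeable available), robust sandwich SEs;
  deaths carried forward as unfavorable; single-visit data fall back to
  plain logistic regression with a warning.
* adjustment rules: baseline NIHSS total can adjust the single-endpoint
  models and the plain GEE; the shift test (no continuous covariates), the
  sliding dichotomy and all with-baseline analyses never adjust.
* no multiplicity correction across the battery — the battery compares
  methods, it does not combine them.

## Degenerate inputs and tie-breaks

Visit windows default to 7–10 / 80–100 / 170–190 / 350–370 days; within a
window the record nearest the midpoint is used, earlier record on ties,
with a logged warning for duplicates. Records after death are a hard
error (toggleable to drop-with-warning) because the absorbing-state
invariant is load-bearing for the Markov likelihood. Empty summary
windows warn and return zero tables. A subject observed alive in a
window who dies later inside it contributes the record nearest the
midpoint, like any duplicate.

## What the acceptance checks establish

The suite verifies: reproduction of the packaged NINDS 90-day count table
(pooled percentages, 619 subjects, 117 deaths); matrix exponentials
against an independent truncated-series oracle (1e-10) and
Chapman–Kolmogorov (1e-9); the exact-death term against numerical
differentiation of the absorption probability (1e-6); the complete-data
MLE against the count/exposure closed form (1e-6); the nesting identities
PPOM(γ=0) ≡ POM, ACAT(2 categories) ≡ logistic, GEE(1 visit) ≡ logistic;
null calibration of the 12-df global LRT (100 replicates, binomial 95%
band) and ≥93% hazard-ratio CI coverage (200 replicates, n = 500/arm);
and the log-linearity of the published restricted-PPOM odds ratios.
Replicate counts are scaled to a single-CPU budget; the statistical
criteria they check are stated alongside each test.
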