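# strokemsm

Multistate Markov modelling and ordinal endpoint analysis for acute stroke
trials measuring the modified Rankin Scale (mRS).

## The problem

The mRS is a 7-level ordinal disability scale (0 = no symptoms, 5 = severe
disability, 6 = death) collected repeatedly after randomization —
typically at 7–10, 90, 180 and 360 days — but conventionally analyzed
once, at 90 days, and often dichotomized (favorable = mRS ≤ 1). Both
habits throw information away. This package is for trial statisticians
and methods researchers who want to analyze the full ordinal scale
longitudinally and to compare that analysis, on equal footing, with the
battery of conventional alternatives.

Its core is a **continuous-time multistate Markov model (MSMM) for panel
data**: the disease process is a Markov chain on the mRS states with
generator Q of transition intensities q_rs (death absorbing, direct moves
only between adjacent disability states), observed only at visit times.
An interval from state r at time t to state s at time t+Δ contributes
P_rs(Δ) = [expm(QΔ)]_rs to the likelihood; a known death date contributes
the absorption density Σ_k P_rk(Δ)·q_k,death instead. Covariates act
proportionally on intensities, q_rs(x) = q_rs·exp(β_rs'x), so exp(β) is a
per-transition hazard ratio; intensities may be piecewise-constant across
epochs. Treatment effects are tested by likelihood-ratio tests — the
global test puts a treatment coefficient on all 12 transitions of the
reduced mRS structure.

Around the core:

* a **synthetic trial generator** (ground-truth Markov trajectories,
  jittered visits, exact death dates, severity-linked baseline covariates)
  so every stage is testable without access to trial data;
* a **PCA baseline predictor** that turns baseline severity covariates
  (NIHSS items, age, glucose, onset-to-randomization time, early CT score)
  into a latent baseline mRS pseudo-observation at time 0;
* the **comparator battery**: logistic regression of the fixed dichotomy,
  linear regression of raw and utility-weighted mRS, CMH shift test,
  proportional odds model, restricted partial proportional odds model
  (linear trend in cut-specific log odds), adjacent-categories logit,
  sliding dichotomy, and repeated-measures GEE — all returning one uniform
  result row (method, outcome, statistic, 95% CI, p).

See `docs/methods.md` for model details, conventions and limitations.

## Worked example

```python
import numpy as np
from strokemsm import (SimulationSpec, simulate_trial, MsmmSpec,
                       global_treatment_test)

spec = SimulationSpec(n_per_arm=310, seed=42,
                      treatment_log_hr={(1, 2): np.log(0.5)})
trial = simulate_trial(spec)

p, fit, _ = global_treatment_test(
    trial.panel, MsmmSpec(covariates=("treatment",)), se=True)
print(fit.summary())
print(f"global treatment LRT p = {p:.4f}")
```

prints

```
Multistate Markov model (panel likelihood)
  states: (0, 1, 2, 3, 4, 5, 6)  absorbing: [6]
  epochs: 1 (breakpoints [])  death_mode: exact
  n subjects: 620  n intervals: 1533
  log-likelihood: -2723.6792  params: 24  converged: True
  hazard ratios:
    0->1 [treatment]: HR 1.313 (0.608, 2.838)
    1->0 [treatment]: HR 1.106 (0.768, 1.591)
    1->2 [treatment]: HR 1.552 (0.505, 4.776)
    ...
    5->6 [treatment]: HR 1.262 (0.733, 2.172)
global treatment LRT p = 0.9821
```

Each row is the multiplicative treatment effect on one transition
intensity with its Wald 95% CI — e.g. `1->2` is the hazard of worsening
from mRS 1 to mRS 2 under treatment relative to control. The simulated
protective effect on that transition (true HR 0.5) produces only ~10
observed 1→2 moves at this sample size, so its estimate is wide and the
12-df global test is far from significant — exactly the power problem,
visible per transition, that motivates richer visit schedules and that
the predicted-baseline extension attempts to address (with caveats
measured and discussed in `docs/methods.md`).

The packaged NINDS t-PA 90-day count table supports the single-endpoint
analyses directly:

```python
from strokemsm import datasets, logistic_endpoint, cmh_shift

panel = datasets.ninds_mrs90_panel()            # 619 subjects at day 90
print(logistic_endpoint(panel).statistics)
# [('OR', 2.0128, 1.4358, 2.8217)]    favorable (mRS<=1) odds ratio
print(cmh_shift(datasets.ninds_mrs90_counts(), scores="ridit").p_value)
# 0.0017124791330441905                the published shift-test p
```

## Command line

```sh
strokemsm simulate --seed 1 --out-dir results        # panel.csv + truth.json
strokemsm summarize results/panel.csv                # arm x state table
strokemsm fit-msmm results/panel.csv --breakpoints 90
strokemsm compare results/panel.csv --methods logistic,pom,shift
strokemsm predict-baseline covariates.csv
strokemsm run --config config.yaml --seed 1 --out-dir results
```

`run` executes a YAML-configured pipeline (input file or simulation block,
chosen analyses, seed) and writes `results.csv` (one row per statistic:
method, outcome, stat_name, estimate, ci_lo, ci_hi, p), `transitions.csv`
(tidy Sankey-style transition counts) and a run log with versions and
seed. Fixed config + seed gives byte-identical outputs.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch: it simulates a
NINDS-scale two-arm trial with the given seed, runs the complete analysis
battery (comparators, GEE, MSMMs with and without the predicted baseline)
and writes the JSON summary to `--out`, leaving the per-analysis results
table beside it.
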