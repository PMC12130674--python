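# Methods

`psdrs` is a Monte Carlo framework for comparing two balancing scores for
confounding adjustment in binary-treatment, binary-outcome cohort studies:

- the **propensity score** (PS), P(T = 1 | X), and
- the **disease risk score** (DRS), P(Y = 1 | T = 0, X),

each estimated by interchangeable probabilistic learners and used for 1:1
greedy caliper matching, with estimation bias and covariate balance tracked
across a grid of scenarios that vary treatment prevalence, outcome risk,
sample size and data complexity.

## Data-generating process

Each simulated cohort has 56 baseline covariates:

| block | columns | distribution | role |
|---|---|---|---|
| normal confounders | X1–X25 | N(0, 1) | affect T and Y |
| binary confounders | X26–X50 | Bernoulli(0.5) | affect T and Y |
| instruments | X66–X70 | N(0, 1) | affect T only |
| risk factor | X71 | Bernoulli(0.5) | affects Y only |

Column names X51–X65 are deliberately absent; the naming follows the
scenario design's variable census, which skips that range. The Bernoulli
success probability is not part of the published design; 0.5 is the
symmetric default and is configurable (`binomial_p`).

Treatment and outcome are logistic:

    T ~ Bernoulli( expit(alpha_T + X beta_T) )
    Y ~ Bernoulli( expit(alpha_Y + X beta_Y + ln(2) * T) )

with every slope drawn i.i.d. uniform[0, 1) — so confounding strength is
itself random — and the true conditional treatment effect fixed at
ln 2 ≈ 0.693 on the log-odds scale. Slopes are **re-drawn every
replicate** by default (`freeze_coefficients=True` fixes them per
scenario), so across-replicate summaries average over confounding
structures as well as sampling noise.

Under the **nonlinear** structure, 20 derived terms enter both linear
predictors with their own uniform[0, 1) coefficients: X6·X26 … X10·X30,
X11·X12, X13·X14, X15·X16, X17·X18, X19·X20, X1³ … X5³, and
X1³·X31 … X5³·X35. Learners never see these terms — they receive the 56
raw covariates only — so the nonlinear scenarios measure robustness to
model misspecification.

### Intercept calibration

Published scenario tables state target marginal rates, not intercepts.
`calibrate_intercept` finds the unique alpha with
mean_i expit(alpha + lp_i) = target to 1e-6 by Brent root-finding (the
objective is strictly increasing in alpha).

- The treatment intercept is calibrated over all subjects' treatment-model
  linear predictors, so the expected treatment prevalence of the replicate
  equals the target.
- The outcome intercept is calibrated over the **realised untreated
  subjects'** outcome linear predictors, so "outcome risk" is the expected
  observed risk among the untreated. Calibrating over everyone at T = 0
  instead (available as `outcome_risk_population="overall"`) targets the
  population counterfactual untreated risk; in heavily skewed nonlinear
  scenarios the two differ noticeably (treatment selects high-risk
  subjects, so the realised untreated subset is systematically
  lower-risk), and the observed-subset reading is the one our calibration
  checks enforce.

The 25 canonical scenarios cross prevalence {0.01, 0.05, 0.1, 0.25, 0.5}
with (n, structure, untreated outcome risk) blocks (500, linear, 0.5),
(10000, linear, 0.5), (500, nonlinear, 0.5), (10000, nonlinear, 0.5),
(10000, nonlinear, 0.02), numbered 1–25 in that order.

## Score estimation

Four learners are registered; any object exposing
`fit`/`predict_proba` can be added to the registry.

| name | model | default grid |
|---|---|---|
| `reference` | unpenalized logistic regression (lbfgs, tol 1e-10) | none |
| `lasso` | L1 logistic (liblinear) on standardized features | C on 10 log-spaced points in [1e-2, 1e2] |
| `gbdt` | histogram gradient-boosted trees | depth {2,3,4} × rate {0.05,0.1,0.3} × rounds {100,300} |
| `mlp` | multilayer perceptron, standardized features | layers {(16,),(64,),(16,16),(64,64)} × L2 {1e-4,1e-2} |

The grids are package defaults (the published design defers its exact
grids to external code) and are overridable per run. `gbdt` answers to
the alias `xgboost`; it is the same gradient-boosted-tree family,
implemented with scikit-learn because no XGBoost build is assumed
present.

Tuned learners are selected by stratified k-fold cross-validation
(default 10 folds) minimizing mean held-out **Brier loss**,
mean((p̂ − y)²); ties keep the earlier grid point, and the winner is
refitted on all rows. When the minority class has fewer cases than
folds, the fold count drops to the minority count (logged); below 2 the
first grid point is used. Stratified folds matter here: at prevalence
0.01 unstratified folds routinely contain no treated subjects.

PS models regress T on the 56 covariates. The full-cohort DRS regresses
Y on [X, T] over everyone and predicts with T forced to 0; the
unexposed-cohort DRS (secondary mode) fits Y ~ X on untreated rows only
and predicts for everyone. All predictions are in-sample and clipped to
[1e-6, 1 − 1e-6] (tree and network learners can emit exact 0/1); the
clip count is recorded.

Both score models receive all 56 covariates, including the instruments
and the risk factor — mirroring a design in which everything measured is
handed to the learner; a confounders-only restriction is available for
the balance metric but not applied by default.

## Matching

1:1 greedy nearest-neighbor matching without replacement on the logit of
the score, caliper 0.2 sample SDs of the logit scores over the whole
cohort (the treated-only SD is a flag). Treated units are processed in
descending logit order (ties by index); each takes the closest unmatched
control within the caliper, ties to the lower control index. Descending
order is a convention chosen for determinism — the greedy family does
not prescribe one — and ascending/random orders are available for
sensitivity checks. Identical scores collapse the caliper to 0, which
still permits exact-score matches.

## Effect and balance metrics

The matched-cohort effect is the treatment coefficient of a logistic
regression of Y on T over the matched rows, ignoring pairing; it equals
the matched 2×2 table's log odds ratio. A zero cell makes the log odds
ratio infinite; such replicates are flagged `separation` and excluded
from bias means (a Haldane–Anscombe +0.5 option exists for sensitivity
analyses). Relative bias is |estimate − ln 2| / ln 2.

Balance is the average absolute standardized mean difference (ASMD) over
the 56 baseline covariates — the continuous SMD
(x̄_T − x̄_C)/√((s²_T + s²_C)/2) for normal columns, the proportion form
(p_T − p_C)/√((p_T(1−p_T) + p_C(1−p_C))/2) for binary ones — before
matching (all rows) and after (matched rows). A column with a zero
denominator contributes 0 when the groups agree and is dropped from the
average otherwise.

Per-cell summaries report each metric's mean with a 95% CI,
mean ± 1.96·SD/√R (the CI of the Monte Carlo mean; ±1.96·SD is a flag).
Each metric averages over the replicates where it is defined: a
separation replicate has no effect estimate but a perfectly valid
matched ASMD and Brier loss. Replicates whose treatment draw is
single-class, whose score target is single-class, or whose matching
yields zero pairs are failures with recorded reasons, never exceptions.

## Noncollapsibility caveat

The simulated ln 2 is a conditional (covariate-level) log odds ratio,
while the matched-cohort estimand is marginal. Odds ratios are
noncollapsible: with strong covariate effects the marginal effect of a
perfectly adjusted analysis is attenuated relative to ln 2, so some
"bias" persists even under ideal matching. The framework replicates the
published definition verbatim and makes no collapsibility correction.

## Known limitations of the synthetic world

The generator emulates independent covariates with logistic treatment
and outcome models; it does not emulate correlated covariates,
measurement error, missingness, time-varying treatment, or outcome
model forms outside the stated interaction/cubic family. A green
directional test therefore establishes behaviour under this stated
world, not under arbitrary observational data.

Two structural floors matter at the extreme corner (prevalence 0.01,
n = 500, i.e. ~5 expected treated subjects):

- an unpenalized PS model separates ~5 treated from ~495 controls
  in-sample, pushing treated scores to 1 and leaving nothing inside the
  caliper — PS cells there fail mostly with `zero_pairs`;
- even perfectly balanced 5-vs-5 matched sets have
  E|SMD| ≈ √(2/π)·√(2/5) ≈ 0.5 per covariate of pure sampling noise, so
  post-matching ASMDs far below ~0.5 are not attainable at that corner,
  and matched 2×2 tables with ~5 pairs and 50% outcome risk frequently
  contain zero cells.

These are properties of the stated world, reported honestly in the
results rather than smoothed away.

## Desk-scale execution choices

The published design runs 100 replicates per scenario. Tests and the
acceptance script scale the expensive n = 10 000 LASSO cells down (50
replicates, a 5-point C grid) to fit a single-CPU desktop budget; the
n = 500 cells run the full 100 replicates. Replicate seeds derive
deterministically from (base seed, scenario id, replicate index), so any
subset of the grid is reproducible in isolation and under parallel
execution.
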