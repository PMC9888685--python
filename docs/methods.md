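# Methods

## Model and estimation

`prismsurv` approximates a surface-varying-coefficient survival model: the
effect of a binary focus variable `x` on log survival time is allowed to
vary over the space of individual-level covariates `z` and, hierarchically,
with a tract-level contextual variable `w`. The approximation is piecewise
constant: a binary tree partitions the `z`-space into cells `A_l`, and in
each cell a linear model

    y = θ0_l + θ1_l·x + θ2_l·x·w + e        (HPRISM; PRISM drops θ2)

is fit. All modelling is on the natural log of survival time in days,
applied once at load. The focus variable is coded so that `θ1 + θ2·w` is
the focus-group-minus-reference difference in predicted log survival, i.e.
the log of the survival-time ratio.

### Censoring: Stute weights

Under random right censoring, ordinary least squares on observed log times
is biased because censored times understate event times. Each node model is
therefore fit by weighted least squares with Kaplan–Meier (Stute) jump
weights computed from the node's own members: order the node's observations
by `y` ascending (events before censorings at ties — the standard KM
convention; ties among events share the order-statistic formula applied
sequentially), then

    d_(1) = δ_(1)/n,
    d_(i) = δ_(i)/(n−i+1) · Π_{j<i} ((n−j)/(n−j+1))^δ_(j).

Censored observations receive weight zero; the weights sum to 1 exactly
when the largest observation is an event. This assumes censoring is
independent of `(x, z, w)` — the same assumption the synthetic generator
encodes.

### Splitting

A candidate split of node τ is scored by the reduction in the sum of
squared *imputed* residuals,

    ΔRSS(s) = Σ_{i∈τ} r̂_i² − ( Σ_{i∈τ_L} r̂_i² + Σ_{i∈τ_R} r̂_i² ),

with `r̂_i = r_i` for events and, for a censored observation, the mean of
the uncensored residuals strictly greater than `r_i` (an estimate of
`E(e | e > r_i)`; when no uncensored residual exceeds `r_i` the raw
residual is kept — a conservative fallback). Raw residuals of uncensored
observations are used in that conditional mean, not weight-standardized
ones. Each daughter term comes from a model *refit* within the daughter —
weights recomputed, residuals re-imputed — matching the fact that the final
model fits separate regressions per cell. The alternative of keeping the
parent's coefficients and only re-imputing within daughters is preserved
behind `TreeConfig(daughter_residuals="parent")`; note that without
censoring that alternative is identically zero, which is why refitting is
the default.

Candidate cutpoints are midpoints between consecutive distinct observed
values within the node (avoids the boundary ambiguity of a strict `<` at an
observed value). Nominal covariates with ≤ 6 observed levels enumerate all
`2^(k−1) − 1` binary partitions; with more levels they are ordered by the
Stute-weighted mean of `y` among uncensored members and scanned as ordinal
(the rpart device). Exact criterion ties are broken toward the
lower-indexed variable, then the smaller threshold / lexicographically
smaller level set. The search is a single exhaustive pass per node; each
candidate is evaluated exactly once, so no memoization is needed.

**Exclusion criteria.** A candidate is feasible only if each daughter has
at least `min_node` records (default 20) and at least
`min_events_per_group` (default 1) uncensored records of each focus group;
in HPRISM mode those uncensored records must additionally span at least two
distinct tracts per group, so that both the race main effect and the
race-by-context interaction remain estimable after the split. If, despite
this, `w` is constant among a node's weighted focus records, the `x·w`
column is dropped for that node (`theta2_dropped`), and downstream
disparity calculations treat `θ2 = 0`.

**Stopping.** A split is accepted only if its ΔRSS is at least `cp` times
the root's imputed-residual RSS (default `cp = 0.01`, the rpart
convention). Growth is depth-first, left daughter first, with node ids in
creation order; the procedure is deterministic given the dataset and
configuration. Cost-complexity pruning and cross-validated `cp` selection
are deliberately not implemented — `cp` is the exposed knob.

**Log-rank alternative.** `criterion="logrank"` scores a split by
`|LR(τ_L) − LR(τ_R)|`, the absolute difference of the two-sample log-rank
statistics comparing focus groups within each daughter, computed on the
original time scale (the log-rank test is rank-invariant, so log vs raw
time is immaterial). The reported ΔRSS of the chosen split is still the
residual criterion, so the `cp` stopping rule stays on a single scale.

### Evaluation

Predictions are log survival times (larger = longer survival). Harrell's C
counts a pair as usable when the smaller observed time belongs to an event;
tied observed times are excluded unless exactly one is an event; prediction
ties score 1/2 (delegated to lifelines' concordance implementation, with a
double-loop oracle in the tests). `repeated_holdout` stratifies by
censoring status, splits 80/20 within strata, grows on the training part
and scores the test part, 100 repeats by default; repeats whose training
sample cannot support a root model are skipped and counted.

### Local variable importance

The Lvimp of covariate `k` at terminal node `l` is the average, over
`n_perm` permutation replicates, of

    (weighted prediction error of node l's members under the tree rebuilt
     on data with column k permuted) − (their error under the original tree).

The permutation is applied across the full dataset and the entire tree is
rebuilt with the identical configuration; "weighted prediction error" is
the Stute-weighted mean squared error, with weights from the node's own
members' KM weights (the weighting was otherwise unspecified; using the
node's own weights keeps the error on the same footing as the node fit).
`n_perm` defaults to 10 — a single noising pass is the literal procedure,
and `n_perm = 1` reproduces it; averaging only reduces Monte-Carlo noise.
Values ≤ 0 mark variables that are not important for that node. Ranks are
within-node, descending by signed value (rank-by-magnitude behind
`rank_abs=True`); ties share the minimum rank.

Andrews curves embed each node's rank-ordered Lvimp vector `c` as

    f_c(t) = c1/√2 + c2·sin t + c3·cos t + c4·sin 2t + c5·cos 2t + …

on `t ∈ [−π, π]` — the standard construction with increasing harmonic
frequencies (a degenerate repeated-frequency variant sometimes seen in
print is not a usable embedding). The map is linear in `c` and 2π-periodic.

### SPADE

Within terminal node `l` the predicted disparity at contextual value `w` is
`d_l(w) = θ1_l + θ2_l·w`. The tract-level estimate gathers each tract's
records across terminal nodes:

    d_m = Σ_l η_lm · d_l(w_m),   η_lm = n_lm / n_m,

where `n_lm` is the number of tract-`m` records in node `l` and `n_m` the
tract's total — the only normalization for which `Σ_l η_lm = 1` per tract.
Because `w` is constant within a tract, `d_l` is evaluated at the tract's
own `w_m`. Tracts with no records receive no estimate (no extrapolation);
tracts with a single record still do, because they inherit the node-level
fits — the borrowing-strength property, contrasted in the tests with a
direct per-tract Kaplan–Meier median difference that is undefined exactly
there. The composite across contextual variables is the per-tract sum of
SPADEs. Robust standardization uses `(d − median)/(1.4826·MAD)` (1.4826
makes the MAD consistent for a normal scale); a zero MAD is an error, not a
silent zero.

## Synthetic data generator

The generator draws from exactly the structure the estimator assumes: a
partition of the covariate space with per-leaf `(θ0, θ1, θ2)`, log event
times `T = θ0 + (θ1 + θ2·w)x + e` with Gaussian noise, and random
censoring from an exponential time on the raw scale whose rate is
calibrated by root-finding so the realized marginal censoring fraction hits
the requested target. Tract sizes are multinomial with a Dirichlet(0.5)
prior — producing the realistic long tail of one-to-two-record tracts that
the SPADE borrowing-strength checks need — and `w` is drawn per tract,
constant within it. The default contextual variable is standardized (mean
0, SD 1), mirroring the usual practice of z-scoring area-level social
determinants before modelling; on that scale the default two-leaf design
uses leaves `(2.5, −0.8, +0.2)` and `(1.5, 0.4, −0.3)` split on a
Uniform(0,1) covariate at 0.5, noise SD 0.25, 20 % censoring, 25 tracts,
focus prevalence 0.4.

What the generator does *not* emulate: informative censoring, competing
risks, time-varying covariates, within-tract heterogeneity of `w`,
measurement error in the social determinants, and the registry artifacts of
real cohort data (duplicate reports, misclassification). Passing tests on
this generator therefore demonstrate correctness of the estimator under its
own assumptions, not robustness to their violation.

## Numerical choices and problem sizes

* Node fits solve the weighted normal equations in closed form (the 0/1
  focus variable reduces the 3×3 system to a scalar plus a 2×2 solve); the
  split scan over numeric cutpoints is JIT-compiled with numba when
  available, with a pure-Python reference path that the tests pin against
  a brute-force oracle.
* The proportional-odds fit is a grouped-table ML (BFGS with analytic
  gradient, converged at gradient norm ≤ 1e-10 per observation), with
  standard errors from the numerically differentiated observed information.
  Although specified for K ≥ 3, the K = 2 case is permitted and reduces to
  the closed-form binary log odds ratio — a useful nested-model identity.
* Fisher's test for 2×K tables with K > 2 uses a fixed-margin Monte-Carlo
  p-value (the `(hits+1)/(reps+1)` estimator) with the draw seeded and the
  rep count recorded; exact network algorithms are out of scope.
* Simulation-based checks in the test suite use: n = 2000, 100 seeds for
  parameter recovery; n = 1000, 20 holdout repeats for the
  HPRISM-vs-PRISM comparison; n = 800 for null-data concordance; n = 400,
  50 seeds, `n_perm = 4` for the Lvimp checks. With the default `cp`, a
  no-signal fit stays at the root reliably once n is a few thousand
  (the cp threshold scales with n while the best noise split grows only
  logarithmically); at a few hundred observations occasional noise splits
  are expected and do not move test-set concordance off 0.5.

## Known limitations

* Single focus variable (`p = 1`); the general multi-focus form is
  documented but not implemented.
* Records with missing essential fields or covariates are rejected — there
  are no surrogate splits.
* Node-level p-values are deliberately not reported: after a data-driven
  search they would be optimistic, and principled corrections (bootstrap,
  selective inference) are out of scope.
* The summed composite SPADE is a pragmatic aggregate; no variance model
  accompanies the tract estimates.
* Choropleth rendering is out of scope: SPADE output is a tract-keyed
  table.
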