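# Methods

## Model

A subject's disease history is a continuous-time Markov process `Z(t)`
on integer-coded states `0..K-1` with transition intensities

    λ_kr(t | V) = λ_kr0(t) · exp( x_kr(V)′ β_kr ),      (k, r) allowed,

where `λ_kr0` is piecewise constant on a shared grid of cut-points
`c_1 < … < c_m` (years) and the multiplier is log-linear in covariates.
Pieces are half-open intervals `[c_j, c_{j+1})`: a time exactly at a
cut-point belongs to the *later* piece.  This tie-break is a convention;
fits of data whose assessment times coincide with cut-points can differ
in the third decimal under the opposite convention.

Everything is parameterized on an unconstrained scale — log baselines
and linear coefficients — which is also the scale on which estimates and
standard errors are reported.  The time origin is a property of each
analysis (disease onset for the onset model; the start of the calendar
window for the calendar-time joint model) and lives in configuration,
not code.

Design terms are (coefficient, covariate, scale) triples.  A term with
no covariate is a constant regressor: joint-model builders use it to
inject indicators (current marker level, treatment status) that are a
deterministic function of the *source state* of a transition, which is
how one parameter vector can serve transitions that differ only in those
indicators.  Parameter sharing across transitions is expressed by
reusing a baseline family name or a coefficient name; the likelihood
machinery sees only the resolved names.

### Transition probabilities and risks

Over `[t0, t1]` the interval is split at interior cut-points and
`P(t0, t1) = ∏_j exp(Q_j Δ_j)` in time order.  The matrix exponential is
an in-house batched scaling-and-squaring routine (scale to 1-norm ≤ 1/2,
degree-13 Taylor in Horner form, square back); a uniformization
(truncated-series) oracle and scipy certify it in the tests to well
below the 1e-8 level the package promises.  State-entry risk
`P(T_target ≤ horizon)` deletes the target's outgoing transitions
(making it absorbing) and reads the corresponding entry of `P`, so it
measures first passage, not occupancy.

### Panel likelihood

Panel data are long-format rows (subject, time, state, covariates).
Consecutive assessment pairs contribute
`log P(Z(a_j) | Z(a_{j−1}), V(a_{j−1}))`; covariates are held at their
last-assessment values across each interval; the first assessment is
conditioned on and contributes nothing.  This is the prospective
likelihood under delayed entry and requires (i) enrolment conditionally
independent of the process given observables, and (ii) Markov
intensities, so that `(Z(L), V)` is a sufficient entry history.  Records
beginning in an absorbing state are rejected at validation; observed
transitions that are impossible under the transition graph yield a
log-likelihood of −∞ with a diagnostic naming the subject and interval
(they are structural zeros, independent of parameter values).

An option marks designated absorbing states (death) as exactly observed:
such intervals contribute the density
`Σ_s P(t0,t1)[k,s]·q_{s,dead}(t1)` instead of an interval-censored
probability.  The option is off by default — the shipped analyses
neglect mortality.

Evaluation is vectorized: all interval segments are assembled into one
batch of generators per likelihood call.  When the distinct
(piece, covariate-row) combinations number at most 64 — categorical
covariates, as in the joint 8-state model — segments sharing a generator
are grouped and `exp(Q·dt)` over the group's durations is computed by
uniformization, `Σ_n Poisson(n; c·dt)·M^n` with `M = I + Q/c`, which is
nonnegative term by term and therefore cannot produce negative
probabilities by cancellation.  Otherwise the batched Taylor route is
used.  The two paths agree to ~1e-12 and are cross-checked in the tests.

### Maximization and inference

`fit_panel_mle` runs L-BFGS-B (quasi-Newton) on the negative
log-likelihood with finite-difference gradients, relative function
tolerance 1e-11 and gradient tolerance 1e-6, starting from crude
occurrence/exposure rates (events per person-year between consecutive
assessments, per baseline family) with zero coefficients, or from a
user-supplied point; optional multi-start jitters the initial point.
Standard errors are the square roots of the diagonal of the inverse
numerically differentiated observed information (central differences,
relative step 1e-4).  A non-invertible information matrix yields NaN
standard errors, never fabricated ones.  Relative risks are `exp(β̂)`
with Wald intervals `exp(β̂ ± 1.96·se)`; 1.96 is used exactly, matching
the published tables.  Exploratory optimizer steps are kept finite by
clipping log-rates at ±30 (rates beyond e^30 per year are far outside
any plausible region); the clip is never active at convergence.

## The joint models

**Onset model** (`build_psa_onset_model`): two states, one transition,
one baseline piece, covariates V1 (age at psoriasis onset − 40, years),
V2 (sex, 1 = male), V3 (HLA-B27, 1 = positive).  An optional death state
with covariate-free mortality intensities reduces to the two-state risks
when those intensities vanish.

**8-state marker/treatment/failure model** (`build_fmt_model`): states
are triples (Z, X, B) coded `4Z + 2X + B` — failure (arthritis
mutilans), elevated inflammatory marker (ESR, dichotomized), biologic
treatment (absorbing once initiated).  Failure states are absorbing for
the analysis: the endpoint terminates follow-up, and post-failure
marker/treatment dynamics are deliberately excluded (the failure state's
marker/treatment labels only record status at failure).  Sub-processes:

* marker flips, intensity `λx_k0(t)·exp(B η_k1 + V′η_k2)` with k = 1
  naming the 0→1 flip and k = 0 the 1→0 flip; the four transitions per
  direction share one baseline and one coefficient set;
* treatment initiation, `λb_0(t)·exp(X φ1 + V′φ2)`;
* failure, `λz_0(t)·exp(X β1 + B β2 + X·B β3 + V′β4)`.

The covariate coefficient vector on the failure intensity is named β4 to
keep it distinct from the interaction coefficient β3.  All baselines are
piecewise constant with cut-points at 5 and 10 years of calendar time,
absorbing secular trends such as growing biologics availability.  The
equations admit all three covariates in every sub-process; published
fits report V3 only for the failure process, so the marker/treatment V3
coefficients are simply zero in the shipped truth values.

**Illness-death × enrolment** (`build_illness_death_enrolment_model`):
six states — healthy/ill/dead outside and inside the cohort — with
pre-enrolment disease intensities `λ°`, post-enrolment `λ`, and
enrolment intensities ρ0 (from healthy) and ρ1 (from ill).  Tying
`λ° = λ` (the `pre_post_shared` flag) is precisely the conditional-
independence condition under which cohort estimates generalize to the
population.  Enrolment intensities are piecewise-constant in time; ρ1
may optionally be scaled by `exp(α·(t − t1))` in time-since-illness,
simulated by thinning.

**Registry selection**: the probability that registry member i has
enrolled by their evaluation time is modelled as
`π_i = expit(intercept + coef′·registry covariates)` — the logistic form
is this package's choice; only the conditional-probability structure is
given in the literature.  The enrolment indicators form a product-
binomial likelihood, maximized by `fit_registry_enrolment` (cross-checked
against an independent GLM implementation in the tests).

## The synthetic-data generator

`simulate_trajectory` samples competing exponentials within each
baseline piece; a candidate sojourn that crosses the next cut-point
advances the clock to the cut-point and redraws, which is exact by
memorylessness.  Visits are a renewal process started at study entry;
the disease path and the visit process are independent by construction.
Type B enrolment simulates the joint disease+enrolment chain until the
recruitment deadline L†, then continues without the enrolment
transitions; enrollees get visits on [entry, censoring] and contribute
one panel row per visit — the state *at that visit only* — with rows
after the first visit in an absorbing state dropped.  Every population
member, enrolled or not, yields a registry record (indicator, evaluation
time, covariates, disease state then).  Per-subject RNG substreams are
derived from the master seed, so enlarging the population leaves
existing subjects' data bit-identical.

Scenario defaults are the package's study conditions:

* `utpc_table1` — onset model at the published point estimates;
  n = 1500; age-at-onset offset V1 ~ Normal(0, 13²) years, sex
  V2 ~ Bernoulli(0.5), HLA-B27 V3 ~ Bernoulli(0.08) (registry-plausible
  prevalence); everyone followed from onset (type A at 0); exponential
  visit gaps, mean 0.8 years; administrative censoring at 20 years.
* `fmt_table2` — 8-state model at the published coefficients; n = 800.
  The published table reports no baseline intensities, so the truth
  baselines are package choices at realistic clinical magnitudes:
  failure 0.03/0.04/0.05 per year across the three pieces, marker flips
  0.25 (0→1) and 0.35 (1→0), biologics initiation 0.06/0.12/0.15
  (rising availability).  30% of subjects start with the marker
  elevated; swollen-joint indicators V1/V2 are mutually exclusive with
  probability 0.25 each; V3 ~ Bernoulli(0.5); censoring at 12 years
  covers all three baseline pieces.
* `enrolment_bias` — illness-death × enrolment with population rates
  λ°01 = 0.15, λ°02 = 0.03, λ°12 = 0.08, enrolment ρ0 = 0.20,
  ρ1 = 0.40 (care-seeking accelerates with illness), recruitment window
  L† = 10 years, censoring at 20.  The `divergence` knob sets
  log(λ01/λ°01); zero reproduces independent enrolment exactly.

Enrolment-rate magnitudes for the motivating cohorts are not published;
the scenario values are invented and labelled as such.  What the
generator does *not* emulate: time-varying swollen-joint covariates
(they are drawn once at baseline and held fixed — the likelihood's
last-assessment convention is exercised, but covariate dynamics are
not), visit processes that depend on disease activity, loss to
follow-up, measurement error in state ascertainment, and competing
mortality in the onset scenario.  Passing recovery tests on these
scenarios therefore certifies the estimation machinery under the model's
own assumptions, not robustness to their violation.

## Scripted experiments

* `reproduce_table_quantities` recomputes every RR and 95% CI cell of
  the two published tables from their printed Est./s.e. columns, the
  20-year onset risks (0.25 male / 0.22 female at the printed
  precision), and the combined biologics effect under an elevated marker
  (`exp(1.081 − 1.657) = 0.56`).  Rounding is half-away-from-zero at two
  decimals.  Because the printed inputs are themselves rounded to three
  decimals, a recomputed cell can land one unit of the last printed
  digit away from the published cell; the shipped tables show a maximum
  absolute deviation of exactly 0.01, consistent with the original
  computations having used unrounded estimates.  The Est./s.e. values
  themselves derive from confidential patient-level data and are
  fixture inputs only.
* `enrolment_bias_study` fits the naive post-entry illness-death model
  to enrollee panel data across a grid of pre/post divergences.  Bias is
  summarized as mean(estimate) − population truth with replicate-based
  standard errors; at divergence 0 it is within Monte-Carlo error of
  zero, at divergence log 2 the fit centers on twice the population rate.
* `registry_identifiability_demo` shows (a) recovery of a logistic
  selection model (intercept −1, illness effect +1) from registry
  enrolment indicators, and (b) that the cohort-only entry likelihood —
  entry times and states, conditioned on enrolment — has a near-flat
  direction over (disease rate, enrolment scale, enrolment illness
  effect), whereas adding the registry's non-enrollee information
  restores a well-conditioned matrix.  The information comparison uses
  the *expected* (Fisher) information at the truth, computed by
  Gauss-Legendre quadrature over the entry time: the observed
  information's smallest eigenvalue is so close to zero that
  single-population estimates of it straddle zero, so the deterministic
  quantity is the honest summary.  The demo scenario uses rare enrolment
  (ρ0 = 0.01/year), the regime in which the enrolment scale nearly
  cancels from the conditional likelihood; the minimum-eigenvalue ratio
  is then ≈ 136.

## Numerical choices

* Matrix exponential: scaling to 1-norm ≤ 1/2, degree-13 Taylor-Horner,
  repeated squaring; truncation error < 1e-14 at that norm.
* Uniformization series: truncated at `x + 8√x + 16` terms
  (Poisson tail < 1e-12 for `x ≤ 30`); larger `x` falls back to
  scaling-and-squaring.
* Optimizer tolerances as above; standard-error Hessian steps
  `1e-4·(1+|x|)`; Fisher-information quadrature uses 64 Gauss-Legendre
  nodes.
* Reported p-value-free intervals use z = 1.96 exactly.
* Problem sizes in the shipped studies (replicate counts, n per
  scenario, 20,000 paths for simulator-fidelity checks) were chosen so
  the full suite runs comfortably on a single CPU while keeping
  Monte-Carlo error well below the effect sizes being demonstrated.

## Known limitations

Semi-Markov intensities, continuous markers, frailty/random effects,
dependent visit processes (a hook exists in the simulator's design but
is out of scope), robust/sandwich variances, score tests, and penalized
or Bayesian estimation are not implemented.  The retrospective
(pre-entry) likelihood component is exercised only in the
identifiability demonstration, not exposed as a general fitting path.
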