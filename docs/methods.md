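# Methods

`pammkit` implements piece-wise exponential additive mixed models (PAMMs)
for recurrent events: a penalized Poisson representation of survival data
in which the hazard is constant within time intervals but varies smoothly
across them, covariate effects may vary smoothly with age, calendar
seasonality enters through a periodic smooth, and within-subject
correlation of recurrent episodes is carried by a Gaussian frailty.

## Data model

A subject is observed on an age window `(entry, exit] ⊆ (0, 728]` days and
experiences episodes at exact days.  Recorded events are collapsed into
episodes by a gap rule: an event opens a new episode only if it occurs
strictly more than `gap_days` (default 14) after the previously retained
event.  Canonicalization is a sequential scan against the last *retained*
event, which is idempotent and order-preserving.

By default a subject remains at risk immediately after an episode.  The
optional `blank_gap` mode instead removes `(event, event + gap]` from
exposure; the data do not identify which convention a given study used, so
both are provided and neither is asserted as canonical.

## Piece-wise exponential data (PED)

The window is partitioned by cutpoints `0 = τ0 < … < τJ = 728` (by default
the unique episode times; a coarser user grid is accepted for speed, at the
cost of making within-interval constancy an approximation).  Intervals are
half-open `(τ_{j-1}, τ_j]` with representative time `t_j = τ_j`.  Each
subject's follow-up is cut into risk spells at episode times; each spell ×
interval overlap becomes one pseudo-observation with

* `exposure` — exact days at risk in the overlap (never zero),
* `offset = log(exposure)`,
* `event ∈ {0, 1}` — whether the spell's terminating episode lies in the
  overlap.

A Poisson log-likelihood on these rows (log link, offset) differs from the
piece-wise exponential survival log-likelihood by a term that does not
involve the parameters, so maximizing one maximizes the other.  The test
suite asserts this equivalence directly on likelihood differences.

For seasonal models each row carries `current_doy`, the calendar
day-of-year at the row's risk-span start,
`((birth_doy − 1 + floor(tstart)) mod 365) + 1`.

## Model structure

With frailty `z_i ~ N(0, σ²)` the fitted hazards are

* model 1: `λ(t | x, z) = exp(β0 + β1 x + f0(t_j) + z)`,
* model 2: `λ(t | x, z) = exp(β0 + β1 x + f0(t_j) + x f1(t_j) + z)`,
* model 3: `λ(t | doy, z) = exp(β0 + g(t_j, doy) + z)`.

`f0`, `f1` are thin plate regression splines (rank `k = 10` by default);
`f1` is a difference smooth multiplied by the 0/1 covariate, so
`HR(t) = exp(β1 + f1(t_j))` and model 2 collapses to model 1 exactly when
`f1 ≡ 0`.  `g` is a tensor product of a cubic regression spline in age
(`S = 8`) and a cyclic cubic regression spline in day-of-year (`M = 8`,
period 365), with one penalty per margin; the cyclic margin forces the
fitted surface and its first two derivatives to match from day 365 to
day 1.  Each smooth is made identifiable by a sum-to-zero constraint over
its reference grid (the unique `t_j` for time smooths, the observed data
rows for the tensor term), absorbed by a QR reparameterization rather than
Lagrange multipliers for numerical stability.  Default basis dimensions
follow common additive-model practice and are arguments, not constants.

In model 3 the tensor term subsumes the baseline age smooth, so no separate
`f0` is included; this is the one place the "exactly one time term" rule is
interpreted rather than literal.

### Thin plate basis

The 1-D thin plate spline over the unique time values is truncated to its
`k − 2` leading radial eigendirections plus the unpenalized polynomial
space (constant, linear).  The penalty is positive semidefinite with null
space exactly the linear functions; after the sum-to-zero constraint the
null space within the term is the (centred) linear direction, so an
infinitely smoothed term degenerates to a line (EDF → 1), which is also how
`EDF = 1` is read in reported fits: an effectively linear log-HR trend.

### Frailty

The random intercept enters as a subject-indicator block with identity
penalty.  Its smoothing parameter is the precision `1/σ²`, so REML
selection of that parameter *is* Gaussian frailty estimation.  All reported
effects condition on `z = 0` (the average subject); no marginalization over
the frailty is attempted.

## Estimation

At fixed smoothing parameters `λ` the penalized Poisson likelihood is
maximized by P-IRLS with step halving (the penalized log-likelihood is
non-decreasing across accepted steps).  The frailty block makes the
penalized information matrix an arrowhead: dense columns plus a diagonal
subject block.  Solves, log-determinants, the marginal covariance of the
dense coefficients and all EDF traces use the Schur complement of that
diagonal block, costing `O(n_subjects · p²)` — this is what makes
2000-subject replicate studies cheap.  The result is numerically identical
to a dense solve (asserted in tests against a generic optimizer on the same
objective, tolerance 1e-5).

Smoothing parameters and the frailty precision are selected by maximizing
the Laplace-approximate restricted likelihood

`REML(λ) = l(β̂) − ½ β̂'S_λβ̂ + ½ log|S_λ|₊ − ½ log|H|`

over `ρ = log λ`, where `H` is the penalized information and `|·|₊` the
pseudo-determinant over the penalty's range space (computed blockwise;
jointly by eigendecomposition for the two-penalty tensor block).  Because
each criterion evaluation contains an inner P-IRLS solve, finite-difference
gradients are noisy; optimization therefore uses a coarse coordinate sweep
(ρ from −10 to 14 in steps of 3, two passes) to locate the basin, followed
by Nelder-Mead with a unit initial simplex.  Penalties are rescaled to unit
spectral norm so the ρ scales are comparable.  Convergence: relative REML
change below 1e-7, inner P-IRLS relative objective change below 1e-11
(tight enough that the intercept-only model reproduces the closed-form
Poisson MLE to 1e-8).

Uncertainty uses the Bayesian posterior covariance `H⁻¹` (penalty as
prior).  Confidence intervals for hazards, hazard ratios and seasonal
surfaces are computed on the linear predictor and transformed
monotonically.  Cumulative-incidence intervals use the delta method on
`log Λ(t)`; a posterior-simulation alternative was considered and not
implemented because the delta method was adequate against the
nonparametric oracle at the tested cohort sizes.

### EDF and smooth tests

Per-term EDF is the trace of the term's block of `F = H⁻¹X'WX`, computed as
`I − H⁻¹S` (so an unpenalized parametric column has EDF exactly 1, and an
infinitely penalized smooth's EDF equals its null-space dimension).  The
"is this smooth zero" test evaluates the fitted curve on the `t_j` grid,
forms its Bayesian covariance, pseudo-inverts at a rank tied to the EDF
(floor, +1 if the fractional part exceeds 0.05), and refers the quadratic
form to a chi-square with that rank.  This is a Wald-type approximation in
the spirit of the tests reported by mgcv-style GAM software; the exact
published variant is not claimed.  Its type-I error is checked by
simulation (200 null replicates) in the acceptance suite.

### Model selection

For each binary covariate, model 1 and model 2 are both fitted; model 2 is
preferred iff the f1 test's p-value is strictly below `alpha` (default
0.05, configurable).  The report carries per-group incidence rates
(`365.25 × exp(β̂0 [+ β̂1])` episodes per child-year), the constant or
averaged HR with 95% CI, the EDF and the p-value — the layout of a
risk-factor summary table.

## Synthetic cohorts

`simulate_cohort` draws event times by Lewis-Shedler thinning against a
per-subject majorant (the grid maximum of the subject's hazard × 1.05 on a
0.25-day grid), so event times are continuous and PED exposures genuinely
non-integer.  The gap rule is applied to the raw event stream exactly as to
real data.  The default scenario uses: n = 1137 subjects, a smooth baseline
peaking near day 105 (≈3.5 months) scaled to an average incidence of 0.3
episodes per child-year, frailty SD 0.5, administrative censoring at day
728, optional exponential dropout.  These defaults describe a plausible
birth-cohort world for testing; they are not estimates of any study's data.

What the generator does *not* emulate: covariate missingness, death as a
competing risk, exposure-lag (cumulative) effects, calendar trends across
enrolment years, or informative censoring.  A green simulation gate
therefore establishes correctness of the estimation machinery under the
stated world, not robustness to those features.

## Numerical choices and edge cases

* Episodes exactly at a cutpoint belong to the interval ending there
  (half-open convention); an episode at day 728 falls in the last interval.
* Ties across subjects share one cutpoint; zero-exposure rows are never
  emitted.
* The linear predictor is clipped at ±30 before exponentiation inside
  P-IRLS; a level of a covariate with zero events triggers a separation
  warning rather than a silent unstable fit.
* `ρ = log λ` is searched in [−10, 14] coarsely; Nelder-Mead may move
  outside.  `λ → ∞` behaviour (collapse to the unpenalized null space) is
  reachable by fixing `lambdas` explicitly.
* Basis construction is deterministic given knots and `k`; repeated
  construction is bitwise stable.

## Known limitations

* Smoothing-parameter selection is REML-only (no GCV/AIC route).
* The frailty distribution is Gaussian only, and reported effects are
  conditional on `z = 0`, not population-averaged.
* The smooth p-value is an approximation; its finite-sample calibration is
  demonstrated by simulation at the tested sizes, slightly conservative.
* The "recurrent episodes" cumulative-incidence curve is defined as the
  conditional-Poisson tail `P(N(t) ≥ k)` at `z = 0` under the fitted
  intensity — a model-based definition chosen because a nonparametric
  per-episode stratification is not available from the fitted object.
* Age is the only timescale; gap-time (time-since-last-episode) models are
  out of scope.
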