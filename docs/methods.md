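# Methods

This note records the statistical model `itseg` implements, the estimation
and testing procedures, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Model

Each unit's outcome decomposes as `y_t = mu_t + r_t` on 1-based integer
ticks `t = 1..n` mapped from the calendar grid (all date↔tick conversion
lives in the ingestion layer).  The mean is piecewise linear with a single
change-point τ, defined as the **first tick of the post phase**: the design
row is `[1, t, I(t >= tau), t·I(t >= tau)]`.  The residual process switches
its parameters at the same boundary: innovations for `1 < t <= tau-1` are
pre-phase, innovations for `t >= tau` are post-phase, and the innovation at
`t = tau` regresses on `r_{tau-1}` *across* the boundary.  This asymmetric
boundary convention (the pre-phase has observations `1..tau-1`, the
post-phase innovations start at `tau`) is applied consistently in the
simulator, the whitening transform, the moment estimators and the
conditional likelihood, so the estimators are exactly matched to the
generative process used to validate them.

Correlation structures per phase:

- **ar1** (default): `r_t = phi_j r_{t-1} + e_t`, `|phi_j| < 1`, marginal
  variance `sigma2_wj / (1 - phi_j^2)`.
- **independent**: `phi_j = 0`; the innovation variance is the marginal
  variance.
- **exchangeable**: compound symmetry within each phase — constant pairwise
  correlation `rho_j` and variance `sigma2_j`.  The whitening transform is
  the symmetric inverse square root of the block covariance.

## Estimation

At a fixed candidate τ, each unit is fit by IRLS: (a) GLS of the segmented
design using the whitening transform `L` built from the current noise
parameters (minimising `||L(y - Xb)||^2`, with covariance `(X'L'LX)^{-1}` —
the innovation variance is folded into `L`); (b) method-of-moments noise
update from the new residuals.  Iteration starts at `phi = 0` (so the first
pass is OLS) and stops when the largest absolute parameter change falls
below `1e-8`, with a cap of 50 iterations; on hitting the cap the last
iterate is returned with a warning and a `converged=False` flag.  In
practice non-convergence is an oscillation between nearly identical
parameter sets and occurs mainly at badly misspecified candidates.

Moment estimators, per phase with `m` observations: `phi_j` is the lag-one
sample autocorrelation of the phase's residual subsequence (clamped to
`[-0.99, 0.99]` to keep marginal variances finite), and the innovation
variance is the phase residual variance times `(1 - phi_j^2)`.  The residual
variance uses denominator `m - 2`, accounting for the intercept and slope
estimated within the phase; this degrees-of-freedom choice keeps the Wald
machinery close to nominal at moderate series lengths.  Each phase must
contain at least `min_segment = 4` observations (2 to pin down the line, 2
more to give lagged residual pairs), which bounds the admissible candidate
range.

For the exchangeable structure the pairwise-product moment estimator of
`rho` is **weakly identified**: residuals from a fit containing a per-phase
intercept sum to approximately zero within each phase, which pins the
estimator near `-1/(m-1)` regardless of the true correlation.  The
structure is provided for completeness and for GLS weighting under a
user-supplied belief, but AR(1) should be preferred whenever serial
dependence is actually of interest.

The global change-point maximises the **conditional log-likelihood** summed
over units (units are independent): the Gaussian log-density of the
innovations `e_t = r_t - phi_{j(t)} r_{t-1}`, `t = 2..n`, conditioning on
the first observation.  A config toggle (`include_first_marginal`) adds the
stationary marginal term for `t = 1`; it is off by default so that the
criterion is exactly the likelihood of the conditional AR decomposition.
For the exchangeable structure the innovation form has no meaning and the
full joint Gaussian log-density is used instead.  Ties across candidates
break to the earliest candidate.  Candidates whose fit fails (rank
deficiency near the grid edges, degenerate residuals) are dropped with a
warning rather than aborting the grid search.

Reported per-unit summaries at τ̂: level change `delta + Delta·tau` (variance
via the linear combination `a'Va`, `a = (0,0,1,tau)`), trend change `Delta`,
adjacent-correlation change `phi_2 - phi_1` (delta-method variance
`(1-phi^2)/m` per phase, AR(1) only; descriptive otherwise), and marginal
variance change (Gaussian-theory `Var(s^2) ≈ 2 sigma^4/m` per phase,
ignoring autocorrelation — a descriptive interval).  All intervals are
Wald-type with standard-normal quantiles, computed **conditionally on τ̂**:
uncertainty in the estimated change-point is not propagated, so intervals
can be optimistic when the likelihood profile is flat.  This conditional
reporting is a known limitation.

## Existence test

For every candidate q the supremum Wald test computes
`W_q = (Cb)'[CVC']^{-1}(Cb)` where `b` stacks the per-unit segmented
estimates, `C` selects the `(delta_i, Delta_i)` entries, and `V` is block
diagonal across units.  `W_q` is referred to chi-square with `2N` degrees of
freedom; the `|Q|` p-values are Benjamini–Hochberg adjusted (step-up), and a
change-point is declared to exist if any adjusted p-value is below α.
Applying BH to p-values or to critical values is decision-equivalent for the
step-up procedure.

Two covariance plug-ins are provided.  The default, `wald_cov="null"`,
evaluates the covariance of the segmented-design GLS estimator under the
noise parameters estimated from the **null** (single-line, single-phase)
model, so the nuisance is estimated from the whole series.  The alternative,
`wald_cov="alt"`, uses the alternative-model IRLS covariance.  The default
was chosen because the two differ sharply in finite samples: with
`n = 100`, `N = 4`, AR(1) `phi = 0.3`, the per-candidate type-I error is
≈ 0.046 under the null plug-in and ≈ 0.14–0.20 under the alternative
plug-in (each phase then contributes only ~half the observations to its own
nuisance estimates, and the plug-in noise in `V^{-1}` inflates the quadratic
form in exactly the way the classical Hotelling correction describes).
Power is retained: ≈ 0.9 at a 2-SD level change and ≈ 1 at 5 SDs (N = 2,
n = 100).

At the family level the BH step-up over a window of strongly positively
dependent candidate tests is conservative (Simes-type): with a calibrated
per-candidate test the measured family rejection rate under the global null
is ≈ 0.028 rather than 0.05 at the conditions above.  Users should read the
existence decision as FDR-safe rather than exactly sized.

Per-unit labels ("effective change-point" / "no change-point") come from
unit-level 2-df Wald tests on `(delta_i, Delta_i)` at τ̂ with the same
covariance convention, BH-adjusted across units at the 0.05 level.  Because
τ̂ is selected by the profile, these labels inherit a mild post-selection
optimism; the global existence decision, which scans all candidates with
multiplicity correction, is the protected inference.

## Synthetic data

The generator draws exactly from the model: piecewise-linear unit means
sharing one global τ, phase-switching AR(1) residuals with the boundary
convention above, and `r_1` drawn from the **pre-phase stationary
distribution** (which makes the closed-form moment checks exact).  Units are
independent; per-unit streams are derived from a single seed via spawned
child sequences, so any unit is reproducible in isolation.  A
`missing_rate` option blanks interior cells of the exported table to
exercise ingestion-side interpolation.

Named presets cover the study conditions used throughout the tests: `null`,
`level-jump` (2-SD level change), `slope-change` (pure trend change, zero
level change at τ), `noise-only-change` (mean unchanged; `phi` rises
0.2→0.6 and the innovation variance falls 1→0.4 — the motivating case of an
intervention that stabilises an outcome without moving its level), and
`biweekly-panel` (4 units, bi-weekly calendar grid from 2010-01-01, n = 193,
about 7 years).  Defaults follow the calibration conditions: `N = 4`,
`n = 100`, `tau = 50`, AR(1) `phi = 0.3`, unit innovation variance.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: non-Gaussian or heavy-tailed innovations,
discrete or bounded outcomes, seasonality and calendar effects, higher-order
(AR(p>1)/MA) dependence, unit-specific change-points, and cross-unit
correlation.  Real panels violating these assumptions can bias both τ̂ and
the existence test in ways the simulation suite will not reveal.

## Numerical and design choices

- Internal ticks are 1-based; τ is the first post-phase tick.  Re-indexing
  `t → t + c` changes the level change by `Delta·c`, so all reported
  effects are tied to this convention.
- `phi` clamped to `[-0.99, 0.99]`; exchangeable `rho` additionally floored
  at `-1/(m-1) + 1e-6` for positive definiteness.
- GLS raises a singular-design error naming the offending candidate if the
  whitened design loses rank; degenerate (zero-variance) residuals raise a
  degenerate-data error.
- Dates: ISO-8601 by default, a strptime format string otherwise; numeric
  ticks accepted.  Grid regularity is validated against the median step
  with 1% relative tolerance; irregular grids are rejected.  Duplicate
  timestamps are an error naming the date.
- Missing data: interior gaps are linearly interpolated on the time grid
  with a warning (imputation slightly biases parameter estimates; complete
  series are preferable).  Leading/trailing missing cells cannot be
  interpolated and are trimmed with a warning.  Units are restricted to
  their common overlapping timestamps before fitting.
- Candidate windows snap to measurement dates: any two ranges whose
  endpoints fall between the same measurements produce identical candidate
  sets.
- Simulation sizes in the verification suite (500 replicates for null
  calibration, 2000 for the reference-distribution check, 200 for recovery
  and consistency, 60 per point of the power curve) were chosen to give
  Monte-Carlo standard errors comfortably inside the asserted tolerances.

## Known limitations

- Conditional-on-τ̂ intervals (no change-point uncertainty propagation).
- Family-level conservatism of the BH-corrected existence decision under
  dense candidate windows.
- Exchangeable dependence is weakly identified from a single series.
- No covariate adjustment, no AR(p>1)/MA(q), no unit-specific
  change-points, continuous Gaussian outcomes only.
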