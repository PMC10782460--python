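# Methods

## Model

`recurprof` fits a marginal proportional-rates model for clustered recurrent
events on a discrete daily calendar grid.  For patient *i* in facility *j*,
conditional on being under observation,

    E{ dN_i(t) | Y_i(t), Z_i(t) } = Y_i(t) · exp{ α_j + Z_i(t)'β } · dμ₀(t),

where Y_i(t) is the at-risk indicator (entry to exit, honouring recorded
gaps), Z_i(t) a p-vector of possibly time-varying covariates, α_j a fixed
facility effect, and dμ₀(t) a non-parametric baseline rate in *calendar*
time.  Using calendar time as the baseline scale lets the model absorb
seasonal and epidemic swings non-parametrically, while other time scales
(e.g. time since disease onset) enter as covariates.  The model is marginal:
it does not condition on a patient's earlier events, so within-patient
dependence is a variance matter, not a modelling one.

Time is integer days on a study window of τ days (default 365).  Intervals
are half-open `(start, stop]`: entries happen at the beginning of a day,
events and exits at the end, with events preceding exits; a covariate value
on an interval applies to all its days.  At most one event per patient-day
is allowed.

## Estimation

Estimation is deliberately decoupled so that thousands of facility effects
never enter a joint Newton solve:

1. **β** maximises the facility-*stratified* Breslow partial likelihood
   (the facility effects cancel inside strata).  Newton–Raphson with
   step-halving, initialised at 0, tolerance 1e-8 on max|U(β)|, at most 50
   iterations.  Strata without events contribute nothing and are skipped.
   A singular information matrix raises an error naming the collinear
   columns; non-convergence (e.g. monotone likelihood) sets a flag and
   warns, never silently returns.
2. **dμ₀** given (β, α) is the Nelson–Aalen occurrence/exposure estimator
   dμ̂₀(t_m) = dN·(t_m)/S⁽⁰⁾(t_m) on the grid of observed event days,
   zero elsewhere.
3. **α** given β is obtained by a fixed-point iteration.  With observed
   facility counts O_j and expected counts
   E_j = Σ_i ∫ Y_ij exp(Z'β̂) dμ̂₀ (note: no α inside E_j), each sweep
   recomputes the baseline at the current α, then sets
   exp(α_j) ← C·O_j/E_j with C = ΣE/ΣO.  The per-facility log likelihood in
   α_j is concave, so the iteration converges; C ("the recentring factor")
   tends to 1 and enforces the identifiability constraint ΣO = ΣE, under
   which exp(α̂_j) = O_j/E_j is exactly the standardised event ratio (SHR)
   and the pooled population's SHR is exactly 1.  Convergence requires
   max_j |Δα_j| ≤ 1e-6; facilities with no events are pinned at the
   sentinel α = −10 (their patients still contribute to risk sets and to
   E_j) and are excluded from the convergence check and from standard
   errors.

All risk-set quantities are computed by a scatter/prefix-sum sweep over
interval endpoints (each interval is active on a contiguous range of
event-day slots), never by splitting records per event; the cost per Newton
or fixed-point sweep is linear in intervals plus facilities × event days.

## Inference

* **β, naive:** inverse observed information of the stratified model —
  valid only under a full intensity model.
* **β, robust:** sandwich I⁻¹(Σ_i U_i U_i')I⁻¹ with per-*patient* score
  contributions U_i, valid under the marginal model with arbitrary
  within-patient dependence.  Within a facility the effect exp(α_j) cancels
  from both the weighted covariate average and the norming factor, so the
  stratified (α-free) quantities are used.
* **α_j, naive:** the information for α_j equals O_j, giving se = 1/√O_j.
* **α_j, robust:** the facility-level sandwich
  V_j = Σ_{i∈j} (O_ij − E_ij·O_j/E_j)² / O_j².
* Variability of β̂ and dμ̂₀ is ignored in the α standard errors: they are
  estimated from the whole population (n patients) while α_j rests on one
  facility (n_j patients); with many facilities the former is negligible.
* Wald intervals on the estimation (log) scale of α.

**Reference-facility contrasts.**  Because the baseline is free, facility
effects are only defined up to the chosen constraint; to compare with a
first-facility-as-reference parameterisation the package evaluates
α̂_j − α̂_1.  The standard error of that contrast is underdetermined by the
naive/robust per-facility formulas alone; the harness defaults to treating
the two facilities as independent, se = √(se_j² + se_1²) (both for 1/√O and
for √V_j), and also exposes the "reference treated as fixed" choice
(se_j alone).  The combined choice is the one under which observed coverage
tracks the nominal level in the independent-gap simulations.

## Standardisation

Indirect: SHR_j = O_j/E_j.  Direct: SHR*_j = E(j)*/ΣO with
E(j)* = Σ_i Σ_m Y_i dμ̂₀ exp(Z'β̂ + α̂_j) the whole-population expected
count at facility j's rate.  Under ΣO = ΣE the two coincide elementwise;
`standardise()` computes both sides independently and reports the numerical
gap (≤ 1e-8 on converged fits).  Alternative reporting constraints
(size-weighted mean α = 0; median α = 0) are available for *output
recentring only* — estimation always uses ΣO = ΣE, the only constraint
under which the equivalence holds.

## Synthetic-data generator

The generator emulates a registry year of dialysis-like hospitalisation
histories; its defaults are the study conditions, not tuning knobs:

* facilities: F = 100 (scenario presets sweep 30–2,000), sizes
  n_j ~ Poisson(mean); a drawn size of 0 is redrawn (an empty facility is
  degenerate); scenario-specific fixed sizes override.
* effects: α₁ = 0, α_j ~ N(0, 0.2²) otherwise; scenarios 5–6 also pin the
  last facility's effect at 0 (the evaluation target).
* covariates (time-constant): five continuous N(0, 0.09), five Bernoulli
  with success probabilities 0.2, 0.28, 0.36, 0.44, 0.52;
  β = (0.1, −0.5, 0.3, 0.22, 0.38) repeated twice.
* entry/censoring: P(B = 0) = 0.8 else uniform{0..364}; at-risk time
  t = min(τ−B, t*) with P(t* = 365) = 0.75 else uniform{1..365};
  exit X = B + t.  Exact enumeration of this law gives a 22.44% probability
  of exit before day 365 and 40.0% probability of a truncated at-risk
  period, and the generator's empirical frequencies match within binomial
  error.
* events: exponential gap times with daily rate ρ₀·exp(α_j + Z'β)·W_i,
  ρ₀ = 0.003, rounded *up* to whole days and accumulated from entry until
  the at-risk time is exhausted; the overshooting gap is discarded.  An
  event whose cumulative gap is d falls on calendar day B + d, at day end.
  W_i ≡ 1, or Gamma(1, 1) frailty in the correlated scenarios — mean 1, so
  the marginal rate is unchanged while gap times become dependent.
* resulting volume: ≈1.27 events per patient, ≈1.6 events per 365 at-risk
  days.

What the generator does *not* emulate: time-varying covariates (exercised
separately through the diagnostics stage builder), facility-size/effect
correlation, seasonal baseline shape (the true baseline is flat, so
baseline-shape recovery is only tested through the O/E diagnostics), and
informative censoring.  Passing simulations therefore certify the
estimators under correct specification and under within-patient frailty,
not under those further departures.

## Monte-Carlo harness

`run_study` generates, fits and summarises per replicate, reporting Bias,
ESD (empirical SD), MSE, ASE (mean naive SE), CP (naive 95% coverage),
sASE and sCP (sandwich versions) for the covariate effects (scenarios 1–4)
or the re-referenced last-facility effect α̂_F − α̂_1 against truth 0
(scenarios 5–6).  Replicates with non-converged fits are excluded and
counted (none occur at the preset conditions).  Everything is reproducible
from a single integer seed via spawned child generators.

Desk-scale problem sizes, chosen as the package's own defaults for quick
studies: 150 replicates in the test suite; 400 (scenarios 3–4), 300
(scenario 5) and 200 (scenario 6) in `scripts/acceptance.py`.  At these
sizes a coverage probability carries a binomial Monte-Carlo error of about
±0.02–0.04 (2 SE), which the tests allow for explicitly.

## Diagnostics

* **Schoenfeld residuals for tied daily data:** per day,
  Σ_{events} Z_i − dN·(t)·Z̄(t), accumulated over calendar bins.  Z̄ uses
  the fit's weighting exp(Z'β̂ + α̂) by default (then the residuals sum to
  approximately the pooled score ≈ 0); an unweighted at-risk mean is
  optional.  Flat residual series support proportionality.
* **O/E series:** weekly observed and expected counts; over the whole
  population they tie exactly (the baseline is estimated from these risk
  sets), so the informative use is per facility subset.  Both (O−E)/E (as
  conventionally plotted) and the Poisson-standardised (O−E)/√E are
  emitted, since only the latter is scale-free.
* **Infection-stage timeline:** a day-resolution state machine for a staged
  epidemic covariate: no-COVID until the first diagnosis day d₁; COVID1 =
  [d₁, d₁+9]; COVID2 from d₁+10 while diagnoses keep arriving within 21
  days of the last one (each diagnosis at day d extends the state through
  d+20); post-COVID thereafter; a COVID-coded hospitalisation while
  post-COVID switches to the absorbing late-COVID state.  Day-inclusion
  conventions (COVID1 includes the diagnosis day; post-COVID starts on day
  d+21) are pinned here because clinical text rarely fixes them; stages
  partition follow-up and only move forward.

## Numerical choices and edge cases

* Newton: init 0, tol 1e-8, max 50 iterations, step-halving against a
  decrease of the log partial likelihood larger than its float resolution.
* Fixed point: tol 1e-6 on max|Δα|, max 2000 sweeps; C trajectory recorded
  (C → 1 is a convergence invariant).
* Linear predictors are clipped at ±500 before exponentiation.
* A facility with events but zero expected count (no at-risk overlap with
  any event day) is impossible for its own event days and raises naming
  the facility.
* Empty residual bins report zero with a flag; zero-event facilities
  report SHR 0, sentinel α = −10, and undefined (NaN) standard errors.

## Known limitations

* Facility effects are constant over the year; a time-varying facility
  effect would need a different parameterisation.
* No shrinkage or random-effects estimation of α; tiny facilities have
  noisy SHRs (the naive SE 1/√O_j is honest about this).
* The α standard errors ignore the (small-F) uncertainty of β̂ and dμ̂₀.
* Ties are handled by the Breslow approximation only — appropriate here
  because events are sparse relative to risk sets on any day.
* The discrete-time variant of the model (per-day event probabilities
  instead of rates) is not implemented.
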