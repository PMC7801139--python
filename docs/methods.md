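# Methods

## Problem and model

`worklife` estimates **working life expectancy (WLE)** and **working
years lost (WYL)** between ages 50 and 63 for a cohort of people who are
at work at a common baseline date, from episode-level register data
(employment spells and benefit spells).

The labor-market process is modelled as a non-homogeneous Markov
multistate process on seven states: *work*, *time-restricted work
disability* (full sickness absence, vocational rehabilitation,
temporary disability pension, or partial disability pension without
concurrent earnings), *unemployment*, *economic inactivity*,
*disability retirement*, *retirement*, and *death*. Structural rules
leave 27 allowed transitions: the four active states communicate with
all six other states, disability retirement can move only to retirement
or death, retirement only to death, and death is absorbing.

For each allowed transition *j → k* a Cox proportional-hazards model is
fitted with **age as the time axis** and **delayed entry** (a person
enters the risk set at their age at baseline, 50–63):

    α_jk(t | z) = α0_jk(t) · exp(β_jk' z),

where z holds occupational-class indicators (reference: upper
non-manual) and/or physical-workload exposure-category indicators
(reference: no exposure). The Markov assumption applies: hazards depend
on the current state and age only, not on history. Analyses run
separately by gender; there is no gender covariate.

The adjusted cumulative hazards A_jk(t|z) = A0_jk(t)·exp(β'z) feed the
**Aalen–Johansen product integral** over the pooled event-age grid,

    P(s, t | z) = ∏_{s < u ≤ t} (I + dA(u | z)),

with off-diagonal entries dA_jk(u) and diagonal −Σ_k dA_jk(u), so each
factor is row-stochastic by construction and P needs no renormalization.

The **expected length of stay** in state j from age s = 50 to the
horizon 63, starting in work, is

    ELOS_j = ∫_50^63 P_{work,j}(50, u) du,

computed exactly for the step-function estimator by left-endpoint
summation over grid intervals. WLE = ELOS_work; WYL in each non-work
state is its ELOS; total WYL = 13 − WLE. Because the rows of P sum to
one at every age, WLE plus the six WYL components equals the 13-year
window identically — this conservation is verified to 1e-8 throughout
the test suite and in the acceptance script.

Uncertainty: **percentile bootstrap**. Persons (not records) are
resampled with replacement at the original size, the entire chain (all
27 Cox fits, product integral, ELOS) is re-run per resample via case
weights, and B = 100 replicates give 2.5th/97.5th-percentile bounds. A
resample in which some transition has no events is legitimate: that
transition contributes no flow. One master seed spawns an independent
substream per replicate.

## State assignment from episodes

Register spells overlap; each calendar day is resolved to one state by
priority, non-working states above work so that WYL are not
understated. Overrides, in increasing priority: residual economic
inactivity < work (earnings or part-time sickness allowance, or partial
disability pension with earnings) < unemployment (any unemployment
benefit or pension, *overruling* concurrent earnings) < time-restricted
work disability (full sickness allowance, vocational rehabilitation,
temporary disability pension, partial disability pension without
earnings) < disability retirement < retirement < death. The source data
do not pin down a tie-break between simultaneous ill-health and
unemployment benefits; ill health above unemployment is this package's
choice, implemented as an ordered overlay that can be reordered in
`worklife.assign._OVERLAYS`-style code if a sensitivity analysis needs
it.

Days are closed intervals; a state change takes effect on the first day
of the winning episode. Censoring at age 63 includes days up to the day
before the 63rd-birthday calendar anniversary (Feb 29 birthdays
anniversary on Mar 1); administrative censoring uses the study end
date. Ages are fractional years = days alive / 365.25.

## Numerical choices

* **Ties**: Breslow approximation, composing exactly with the Breslow
  baseline estimator; day-grain ages make ties frequent. The in-package
  Newton solver supports case weights (bootstrap) and left truncation.
  Covariates are centered internally (the partial likelihood is
  location-invariant) for numerical stability.
* **Separation**: with few events a transition's partial likelihood can
  be monotone (infinite MLE). The solver detects the likelihood
  plateau, bounds |β| at 20 (hazard ratios beyond e±20 are numerically
  infinite), logs a warning, and continues; a non-positive risk-set sum
  encountered mid-iteration is treated as an over-long step and halved.
* **Zero events**: β = 0 with an identically zero baseline (identity
  factor in the product integral), logged.
* **Hazard-increment capping**: under extreme covariate profiles an
  adjusted increment can push a one-step diagonal below zero; the row's
  increments are scaled so the diagonal is 0, with a warning
  (`cap_increments=False` raises instead).
* Convergence: Newton with step halving, gradient fallback when the
  information matrix is singular; tolerance 1e-10 on the step, max 50
  iterations.

## Synthetic register generator

No real register data are available to this package, so
`worklife.simulate` generates cohorts with the structure the estimator
assumes: everyone is at work on the baseline date (2005-01-01 by
default) with entry age uniform on [50, 63) — uniform because no entry
age distribution is prescribed and uniform exercises the delayed-entry
machinery across the whole window; follow-up ends at the study end date
(2014-10-31 by default) or age 63. Latent careers are drawn from a
continuous-time Markov chain with piecewise-constant baseline
intensities over age bands (competing exponentials re-drawn at band
boundaries) and proportional covariate effects, then rendered into raw
spells: earnings for work, benefit spells for other states, nothing for
economic inactivity (the residual state). A configurable fraction
(default 0.2) of benefit spells gets a spurious overlapping earnings
spell, so the day-level priority rules downstream do real work; the
rendering is constructed so that priority resolution recovers the
latent career exactly, which the tests exploit as a round-trip
identity.

The default scenario's intensities were chosen once to be
epidemiologically plausible for 50–63-year-old workers — reference
profile spends ≈ 9.7 of 13 potential years at work; sickness spells are
short and mostly reversible (time-restricted disability → work at
3.0/yr); disability retirement is fed mainly through time-restricted
disability; retirement intensity jumps from 0.007 to 0.55/yr at the
early-retirement age 62 — and the log hazard ratios point the way
occupational gradients point in register studies (manual class and high
physical workload raise ill-health and unemployment exits; the
self-employed rarely enter unemployment). **They are test fixtures, not
estimates of any real population**: the source registers are
confidential and no fitted per-transition hazard ratios are published,
so no parameterization could claim to reproduce them. Magnitudes live
in `worklife.simulate.default_intensities` / `default_effects`.

The synthetic JEM covers seven occupation codes with gender-specific
exposure probabilities for the five physical workload factors (heavy
physical work, kneeling/squatting, manual handling of heavy loads,
hands above shoulder level, awkward trunk posture), dichotomized at
0.40 (inclusive) and counted into categories none / 1–3 / 4–5. The
threshold is configurable for sensitivity analyses. Occupation is
measured once at baseline; exposure is not time-varying.

What the generator does **not** emulate: benefit amounts and the
300/500-day unemployment-benefit clocks, calendar-period legislative
changes, emigration (lumped into economic inactivity), occupational
mobility after baseline, and any correlation between entry age and
covariates. Passing tests therefore demonstrate correctness of the
estimator chain under the model's own assumptions, not fidelity of any
particular WLE value to a real population.

## Verification design

Every stage is checked against an independent oracle: transition
enumeration against a brute-force pair enumerator (including randomized
rule sets); the Cox solver against a loop-coded partial likelihood
maximized numerically, against lifelines on tie-free data (Efron equals
Breslow without ties), and against subgroup Nelson–Aalen curves; the
product integral against a naive matrix-product implementation (exact
agreement at β = 0) and against matrix-exponential solutions of the
Kolmogorov forward equations for constant intensities; ELOS against the
closed form (1 − e^(−13λ))/λ for the two-state model and against mean
latent state occupancy; Wald intervals and the percentile bootstrap
against nominal coverage in repeated simulation. Problem sizes used in
the routine suite: n = 50 000 persons for closed-form limits and rate
convergence, n = 20 000 × 100 replicates for Wald coverage, n = 400 ×
100 outer replicates with B = 100 for bootstrap coverage, smaller
fixtures elsewhere.

## Known limitations

* The marginal process of a heterogeneous Markov population is not
  Markov; pooled (covariate-free) estimates are interpreted as
  population-averaged occupation probabilities.
* Transition-specific models are fitted independently; correlated
  frailty across transitions, time-varying covariates, and semi-Markov
  (duration-in-state) effects are out of scope.
* With B = 100 the percentile bounds are coarse (resolution ~1/40 of
  the replicate spread); no normal-approximation alternative is
  offered.
* Whether published stratified tables derive from single-covariate
  models or a joint model evaluated at profiles is ambiguous in the
  source material; both modes are exposed (`covariate_mode` = class,
  exposure, joint), with class/exposure single-covariate modes as the
  default reading.
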