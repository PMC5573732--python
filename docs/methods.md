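# Methods

## The model

The attentional drift-diffusion model (aDDM) describes a binary perceptual
choice between a left and a right stimulus as the first passage of a
relative decision value (RDV) through one of two absorbing barriers. The
RDV starts at 0; every 10 ms it changes by `μ + ε`, with `ε ~ N(0, σ²)`.
Crossing +1 produces a left choice, −1 a right choice. The drift `μ` is
gated by gaze:

- left item fixated: `μ = d (r_left − θ r_right)`
- right item fixated: `μ = d (θ r_left − r_right)`
- otherwise (latency before the first fixation, blank fixations,
  inter-fixation transitions): `μ = 0`.

`r ∈ {0, 1, 2, 3}` is the relative proximity of a stimulus to the target
orientation, `3 − |Δ|/5` for an angular distance `Δ ∈ {−15°, …, +15°}` in
5° steps. The three free parameters are the integration speed `d` (> 0,
per 10 ms step), the attentional discount `θ ∈ [0, 1]` applied to the
unfixated item (θ = 1 recovers the standard DDM, in which gaze is
irrelevant), and the increment noise `σ` (> 0, per 10 ms step). Barriers
at ±1 and the 10 ms step are conventions, not parameters: scaling the
barriers, `d` and `σ` jointly leaves the model's predictions unchanged.

Noise accrues at the same `σ` in every regime, including latency and
transitions. Whether noise accrues during transitions is not pinned down
by the task description; we assume it does, by analogy with the latency
period, and expose it as `ModelParams.noise_in_none`.

The fixation process is exogenous: fixation locations and (maximal)
durations may depend on the stimuli but not on the RDV. A maximal duration
is drawn at each fixation's onset and runs its course unless a barrier is
crossed first, in which case the final fixation is truncated.

## Fixation-stream cleaning

Recorded gaze events are item fixations or "blank" fixations. Trials whose
blank time exceeds 50% of the reaction time are discarded. A blank between
two same-item fixations (blink/tracker dropout) is absorbed into a single
fixation; no maximum absorbable blank duration is imposed, since none is
defined for the task. A blank between different-item fixations is kept as
an inter-fixation transition. Leading blank time is the latency; trailing
blanks are dropped (only between-fixation blanks are transitions). All
durations are stored in integer milliseconds; binning to the 10 ms model
grid happens downstream, by flooring.

## Likelihood

The likelihood of one trial's (choice, RT), conditional on its observed
fixation stream, is computed by deterministic propagation of a discretised
probability mass over the RDV axis. `n_states` grid points span [−1, +1]
(odd, so one state sits exactly at 0, the starting point); the endpoints
are absorbing. Each 10 ms step applies a Gaussian transition kernel with
the event's drift and sd σ. Interior mass is assigned by midpoint-rule
integration of the normal density and rescaled so that interior plus
absorbed mass exactly matches the true Gaussian split across the barriers
— total mass is conserved to machine precision, and exact barrier hits
count as crossings. The trial's likelihood is the mass newly absorbed at
the observed RT bin on the chosen side, floored at 10⁻¹⁰ before taking
logs. The truncated final fixation needs no special handling: absorption
is read out at the observed RT regardless of how long that fixation would
have lasted. If event time and RT disagree (rounding residue), the final
event is stretched or trimmed to cover exactly the RT.

Runs of equal-drift steps are advanced with cached binary powers of the
kernel, which makes the grid search fast without changing the arithmetic
(matrix powers of one kernel commute). Degenerate kernels (σ far below the
state spacing) place the surviving mass on the state nearest the
deterministic landing point.

Numerical resolution: `n_states = 101` by default; tests and the
acceptance script fit at 71 (and validate that doubling the resolution
changes trial log-likelihoods by well under 1%). The Monte-Carlo
cross-check (propagation vs 10⁵ forward simulations per case) is run at
501 states.

## Fitting

Maximum likelihood by iterative grid refinement. Step 1 evaluates the
27-point grid Ω₁ = {0.001, 0.005, 0.01} × {0.1, 0.5, 0.9} ×
{0.01, 0.05, 0.1} for (d, θ, σ). Each subsequent step builds the cross
product of {x − Δ/2, x, x + Δ/2} around the incumbent, where Δ is the
previous per-parameter step, and stops when the best log-likelihood
improves by less than 1% (relative). Because Ω₁'s d and σ sets are
unevenly spaced, the initial step is defined as half the set's span. Ties
break to the lexicographically smallest triple; θ is clipped to [0, 1], d
and σ floored at 10⁻⁶. The DDM fit is the same search with θ pinned at 1.
The odd/even split is by trial index parity within subject; odd trials are
fitted, even trials held out.

At desk-scale datasets (|log L| ≈ 4–8 × 10³) the 1% rule stops after 2–4
refinements, leaving final grid steps of roughly ±0.002 (d), ±0.2 (θ),
±0.02 (σ); parameter-recovery claims are made relative to those final
steps, not to an absolute precision the stopping rule never buys.

## Out-of-sample simulation

Empirical fixation pools are built from held-out trials: latencies,
transitions, and item-fixation durations partitioned into first / second /
other-middle fixations, the item fixations keyed by
Δr = r_fixated − r_unfixated ∈ {−3, …, +3}. Each trial's final fixation is
excluded (truncated, hence endogenous). Simulation draws a latency, then
alternates item fixations (first to the left with probability
`p_first_left`; the group reference value is 0.65) separated by
transitions, all sampled with replacement from the pools. Runs that cross
a barrier during a latency or transition are discarded and redrawn, with
the discard count reported. Empty (class, Δr) cells fall back to the class
pooled over Δr, then to pooled other-middle fixations, each fallback
logged; empty latency/transition pools mean those periods are absent from
the data and are treated as zero duration.

Three prediction exercises share per-(r_left, r_right) banks of simulated
(choice, RT, net fixation time): unconditional sampling (the DDM exercise
— gaze is uninformative at θ = 1); sampling conditional on the observed
net fixation time (nearest-neighbour window starting at ±100 ms, doubling
until ≥ 50 candidates; the task description states no tolerance); and
re-simulating with the trial's realized fixation path, extended with
pool-sampled fixations if no barrier is crossed by the observed RT. The
reference bank size is 100,000 per stimulus pair; tests and the acceptance
script use 4,000–20,000.

## Behavioural summaries

Curves are pooled per-bin means with normal-approximation 95% CIs. Choice
ease is |r_left − r_right| (equidistant trials form an ease-0 bin and
either choice counts correct). Corrected choice probability subtracts from
each trial's choice indicator the dataset's mean choice rate at the same
Δr; net fixation time is binned at 200 ms. Pooled logistic/OLS/WLS
regressions replace the mixed-effects models used on real multi-subject
data — the slopes here are descriptive, and subject random effects are
orthogonal to the computational pipeline. The goodness-of-fit statistics
are Efron's pseudo-R² in its squared-correlation form, and weighted least
squares on (subject bin mean − model bin mean) with inverse-variance
weights, where non-significant coefficients indicate a good fit (an exact
model match has zero residual variance and is reported as p = 1).

## Gaze-manipulation protocol (minimum-exposure task)

One item per trial is the bias-target: it appears first, the other item
follows after an onset lag; the display ends as soon as cumulative
exposure reaches 800 ms (bias-target) and 200 ms (other), capped at 3 s
(timed-out trials are excluded, their fraction reported). The lag credits
the bias-target's exposure as display time; after onset, exposure accrues
through overt fixations — the hybrid accounting the task prescribes. The
lag is calibrated by a 3-down/1-up staircase (start 300 ms, step 30 ms,
bounds 100–500 ms, 48 trials, counter reset on each decrease and on any
ineffective trial; the lag in force at trial 48 is kept).

The simulated agent fixates the bias-target from stimulus onset (covering
the lag), then alternates per the empirical pools. The RDV integrates with
gaze-gated drift, absorbing at ±1, and is frozen at the stopping time; the
choice is its sign, ties broken at random — the task prompts the choice
only after the display ends, and no post-prompt deliberation is modelled.
A trial is *effective* if it did not time out and the bias-target
accumulated the larger fixation credit.

## Synthetic data

The generator emulates the orientation-matching task: 42 stimulus
conditions (ordered Δ pairs, Δ_left ≠ Δ_right) balanced within subject;
a gamma latency (mean 200 ms), alternating fixations separated by gamma
transitions (mean 100 ms); first fixation left with probability 0.65;
fixation durations gamma with mean
`base + 30·r_fixated + 20·(r_fixated − r_unfixated)` ms (bases 400 ms
first, 650 ms middle; shape 10), reproducing the observed lengthening of
fixations with the fixated item's proximity and proximity advantage, at
magnitudes of roughly 30 ms and 18–20 ms per proximity unit for first
fixations. Durations are quantised to 10 ms at generation so
generator and likelihood share the grid. Defaults produce ≈ 2.1 s mean RT
and ≈ 3.4 fixations per trial at the reference parameters
(d = 0.0041, θ = 0.36, σ = 0.063). Choices and RTs come from the forward
model itself; every trial derives its own seed from the master seed, so
datasets are bit-reproducible and single trials reproducible in isolation.

What the generator does not emulate: subject heterogeneity (all trials
share one parameter triple), target-memory drift across blocks, oculomotor
detail (saccade kinematics, gaze position within an item), and any
feedback from the decision state to fixations (the model's own core
assumption). Passing tests therefore certify the pipeline's internal
consistency — likelihood vs simulator, estimator recovery, bias mechanics
— not the model's adequacy for any particular real dataset.

## Properties worth knowing

- **Truncation selection.** Realized non-last fixations are a biased
  sample of the drawn maximal durations: long draws are more likely to
  contain the barrier crossing and become (excluded) last fixations.
  Duration-vs-proximity slopes estimated from realized fixations are
  therefore attenuated, mildly for first fixations (the RDV starts far
  from both barriers) and substantially for middle fixations. Recovery
  tests quantify slopes on first fixations.
- **A null that needs care.** At θ = 1 the corrected-choice-vs-net-time
  slope is not exactly zero when the first fixation goes left with
  p = 0.65: the expected net fixation time given the trial's timing is
  then nonzero and covaries with choice through the crossing time (with
  drift interrupted by latencies/transitions, accuracy is not constant in
  RT). This is an RT-mediated artifact of the fixation process, not a gaze
  effect on the integrator; it vanishes under a symmetric first fixation,
  which is how the θ = 1 null is tested.
- Last fixations are shorter than middle fixations at any θ — truncation
  by the barrier crossing does not require an attentional bias.
- Non-terminating simulations are cut at 20,000 steps (200 s) and reported
  as censored, never dropped silently.

## Problem sizes

Defaults used by the test suite and acceptance script: datasets of 2–4
subjects × 336 trials (one session is 12 blocks of 28), fitting at
`n_states = 71–101`, banks of 4,000–20,000 simulations per stimulus pair,
400 simulations per condition for out-of-sample summaries, and 6,000
manipulation trials per θ level. The full suite runs in about 2 minutes,
the acceptance script in under a minute.
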