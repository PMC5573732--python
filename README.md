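# addm

Attentional drift-diffusion modelling of two-alternative perceptual
choice: a complete, tested pipeline from raw fixation streams to fitted
parameters, out-of-sample predictions, and gaze-bias analyses.

## The problem

When the two stimuli of a perceptual comparison sit at different screen
locations, they are inspected through alternating fixations — and the
momentary focus of gaze may itself sway the decision. The attentional
drift-diffusion model (aDDM) formalises this: a relative decision value
(RDV) starts at 0 and accumulates noisy evidence every 10 ms until it hits
an absorbing barrier at +1 (choose left) or −1 (choose right). The drift
is gated by gaze,

```
μ = d (r_left − θ r_right)   while fixating the left item
μ = d (θ r_left − r_right)   while fixating the right item
μ = 0                        before the first fixation, during blank
                             fixations and transitions
```

where `r ∈ {0,1,2,3}` is each stimulus's relative proximity to a target
orientation (`r = 3 − |Δ|/5` for angular distance Δ in 5° steps up to
±15°), `d` scales integration speed, `σ` is the per-step noise sd, and
`θ ∈ [0,1]` discounts the unfixated item. At `θ = 1` the model collapses
to the standard drift-diffusion model (DDM) and gaze is irrelevant; at
`θ < 1` shifting gaze toward an item causally biases choice toward it.

The package is aimed at decision-modelling researchers who want to fit
this model to trial-level eye-tracking data (stimuli, choice, RT, ordered
fixation stream), test whether gaze carries predictive information beyond
the stimuli, and simulate gaze-manipulation experiments — or audit all of
the above on synthetic data with known ground truth.

## What's inside

| module | contents |
| --- | --- |
| `addm.preprocessing` | trial/fixation CSV I/O, blank-fixation cleaning rules, proximity coding |
| `addm.model` | the aDDM generative process and single-trial simulation |
| `addm.pools` | empirical fixation pools (first/second/other-middle × Δr) |
| `addm.likelihood` | deterministic fixation-conditional likelihood (state-space propagation) and the iterative grid MLE; DDM fit via θ = 1 |
| `addm.simulate` | condition-level simulation, prediction banks, the three out-of-sample prediction exercises |
| `addm.analyses` | psychometric/fixation curves, corrected choice probabilities, Efron pseudo-R², WLS goodness-of-fit |
| `addm.experiment2` | minimum-exposure gaze-manipulation protocol: stopping rule, onset-lag staircase, simulated causal-bias experiment |
| `addm.synthetic` | ground-truth dataset generator and parameter-recovery harness |

A thin `addm` command-line interface wraps the library
(`addm clean / fit / predict / analyze / synth / recover / exp2 /
simulate-trial`; see `addm --help`).

## Worked example

Generate a synthetic session at the reference parameters
(d = 0.0041, θ = 0.36, σ = 0.063), fit both models on the odd-numbered
trials, and measure the gaze biases:

```python
from addm import (SyntheticConfig, generate_trials, clean_dataset,
                  grid_mle, fit_ddm, LikelihoodSettings, bias_report)

config = SyntheticConfig(n_subjects=4, trials_per_subject=336, master_seed=42)
cleaned, log = clean_dataset(generate_trials(config))
odd = [t for t in cleaned if t.parity == "odd"]

settings = LikelihoodSettings(n_states=71)
addm_fit = grid_mle(odd, settings=settings, improvement_tol=1e-3)
ddm_fit = fit_ddm(odd, settings=settings, improvement_tol=1e-3)
print(f"aDDM fit: d={addm_fit.params.d:.5f} theta={addm_fit.params.theta:.3f} "
      f"sigma={addm_fit.params.sigma:.4f}  logL={addm_fit.log_likelihood:.1f}")
print(f"DDM fit (theta=1): d={ddm_fit.params.d:.5f} "
      f"sigma={ddm_fit.params.sigma:.4f}  logL={ddm_fit.log_likelihood:.1f}")

rep = bias_report(cleaned)
print(f"P(choose last-fixated item | equal proximity) = "
      f"{rep.p_choose_last_at_dr0:.3f} (n={rep.n_dr0})")
```

prints

```
aDDM fit: d=0.00444 theta=0.425 sigma=0.0584  logL=-4172.8
DDM fit (theta=1): d=0.00331 sigma=0.0613  logL=-4221.0
P(choose last-fixated item | equal proximity) = 0.583 (n=187)
```

Reading the numbers: the free-θ fit lands near the generating triple and
beats the θ = 1 restriction by ~48 log-likelihood units — the estimator
detects the attentional discount. Even when the two stimuli are equally
close to the target, the last-fixated item is chosen 58% of the time: the
gaze bias the model exists to capture. (The default `improvement_tol` of
0.01 is the reference search schedule; the stricter 1e-3 used here buys
finer final grids.)

## Limitations

See `docs/methods.md` for the full model description, numerical choices
(state-space resolution, empty-pool fallbacks, tie-breaking), what the
synthetic generator does and does not emulate, and known properties such
as truncation-selection attenuation of fixation-duration slopes.
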