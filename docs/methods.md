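# Methods

## Model

The package models trial-by-trial adaptation to an imposed sensory-feedback
delay as scalar Kalman filtering. The latent state is the response-lead
adjustment (seconds, relative to the participant's own baseline timing)
needed to re-align action and consequence. On each trial the imposed delay
`D_t` (milliseconds, converted to seconds) is fed to the learner as a noisy
measurement of that state. The recursion is the textbook one: the prior
mean carries over from the previous posterior, the prior variance adds the
process variance, and the update moves the estimate toward the measurement
by the gain fraction K = prior variance / (prior + measurement variance).

One published presentation of this update prints the innovation with the
opposite sign (prediction minus measurement), which would drive the
estimate *away* from the feedback and contradicts the accompanying verbal
description. We implement the standard form, X̂ₜ = Xₜ⁻ + K(Xₜᵐ − Xₜ⁻), and
likewise treat the gain formula as exact rather than approximate.

The contribution of the model is the measurement-noise law. The stationary
filter (SKF) uses a constant measurement variance (σ₀ᵐ)². The
non-stationary filter (NSKF) lets it grow linearly with the delay:

    (σ_tᵐ)² = (σ₀ᵐ)² + Δ(σᵐ)² · D_t

Delayed feedback is harder to bind to the action that caused it and
interval estimates lose precision as intervals grow, so larger
perturbations are effectively measured more noisily; the gain falls as the
perturbation grows, and adaptation stalls short of the perturbation.
Δ(σᵐ)² = 0 recovers the SKF identically (asserted in tests to 1e-12
against an independently coded reference filter).

## Parameters and units

| parameter | meaning | unit | default |
|---|---|---|---|
| `x0_prior` | initial state estimate | s | 0 |
| `var0_prior` | initial state-estimate variance | s² | 0.25 |
| `process_var` | per-trial drift of the world (σᵖ)² | s² | 4·10⁻⁶ |
| `base_meas_var` | feedback noise at zero delay (σ₀ᵐ)² | s² | 0.0010 (MC) / 0.0015 (UC) |
| `delta_meas_var` | noise growth per ms of delay Δ(σᵐ)² | s²·ms⁻¹ | 1.7·10⁻⁴ (MC) / 3.7·10⁻⁴ (UC) |

Internal units are seconds and s² throughout; delays stay in milliseconds
and Δ(σᵐ)² is therefore an s² increment per ms. The condition defaults are
the fitted multisensory (MC) and unisensory (UC) values of the study the
package emulates; baseline response SDs of √0.0010 ≈ 32 ms are realistic
for button-press timing. Variances are floored at 1e-15 s² so degenerate
configurations cannot divide by zero.

A wide initial state variance (0.25 s²) makes the very first update follow
the measurement almost entirely; it collapses within a few trials, so the
baseline phase ends at the zero-delay steady state regardless.

## Fitting

Only Δ(σᵐ)² is free. (σ₀ᵐ)² is fixed to the unbiased variance of the
session's baseline-phase response times — response scatter with no
perturbation is the observable proxy for the feedback noise of the
unperturbed state (it overestimates it, since motor execution noise is
included, but condition differences survive). The loss is the sum of
squared differences between the filter's one-step-ahead prediction (the
prior mean, its forecast before seeing the trial's feedback) and the
response times, centred on the session's baseline mean so the filter
tracks adjustment from the participant's idiosyncratic baseline. By
default all trials enter the loss; `adaptation_only=True` restricts it to
the perturbation phase.

The estimate is constrained to Δ ≥ 0 (negative noise growth is not
meaningful here). The optimiser is deterministic: a 200-point scan of
[0, 10⁻² s²·ms⁻¹] brackets the minimum and Brent's bounded method refines
inside the bracketing cell, so fits reproduce bit-for-bit; hits on the
upper bound raise a warning and flag the result. On noiseless
self-generated data the objective is numerically unimodal at the
generating value and is recovered to 1e-6.

Condition summaries average the per-session baseline variances and Δ
estimates and attach 95% percentile bootstrap intervals over participants
(10,000 resamples by default, seeded).

## Synthetic sessions

The generator emulates the timing experiment: 270 trials per session (135
undelayed baseline trials, then the consequence delayed by 1 ms per trial
up to 135 ms), ball speeds {20, 23, 26} cm/s and times-to-contact {1.0,
1.2, 1.4} s balanced over their nine combinations. The simulated
participant is an NSKF learner with the condition's parameters; its
response on trial t is the learned adjustment entering the trial plus a
baseline bias (default 0) and Gaussian execution noise (`motor_sd`,
default the square root of the condition's baseline variance). One RNG per
session, draws in trial order, so identical seeds give byte-identical
sessions.

Deliberate simplifications, and what they imply for the tests: the agent
learns from the *noiseless* imposed delay exactly as the fitted model
assumes (self-consistency is what makes parameter recovery a meaningful
check — it validates the estimation machinery, not the model's truth in
real behavior); execution noise adds response scatter but does not
perturb learning; the speed/TTC covariates are carried for format
fidelity only. Passing tests therefore demonstrate that the pipeline
recovers what it assumes, not that real participants are NSKF learners.

For cohorts probing the variability-adaptation correlation, agents are
made self-consistent in a second sense: their baseline measurement
variance equals their execution variance and their Δ(σᵐ)² scales with it,
mirroring the proportionality seen between the two fitted conditions.
Without that coupling, execution noise alone generates no
variability-adaptation relation.

## Behavioral statistics

Moving averages are trailing with partial windows at the series start
(output length equals input length; window 10 by default). The
variability-adaptation analysis correlates per-session baseline variance
with the *sum* of adaptation-phase response times (Pearson, df = n−2,
two-sided p); at a fixed trial count the sum and the mean give identical
correlations. The condition contrast is a paired one-sided t-test of mean
adaptation response times, multisensory greater; zero-variance difference
vectors yield an infinite t resolved to p = 0 or 1 by the sign and
flagged.

## Paradigm simulations

Stationary, washout and variable-block-length paradigms are forward runs
of the filter (no randomness anywhere in this path). Simulations carry
the baseline-collapsed state variance into the perturbation block rather
than resetting it — a continuous run, which is what produces the slow
(~273-trial at the MC parameters, 5% tolerance) convergence under a
stationary 135 ms perturbation. The convergence tolerance is 5% of the
target by default; tightening to 3% lengthens counts, loosening to 10%
shortens them, without changing orderings. A zero target requires an
absolute tolerance instead (fractional bands are empty at zero).

Time constants come from least-squares fits of
x(t) = asymptote + amplitude·exp(−t/tau), t in trials from phase onset
(1-based). Fitting profiles tau over a log-spaced grid — asymptote and
amplitude are conditionally linear and solved in closed form — then
refines all three parameters locally; constant segments return amplitude
0 with tau flagged unidentifiable. De-adaptation is roughly an order of
magnitude faster than adaptation at the MC parameters (tau ≈ 7.6 vs ≈ 106
trials): the block's unreliable delayed feedback lets state uncertainty
accumulate, so when reliable zero-delay feedback returns the gain jumps.
The same mechanism makes washout weakly faster after longer blocks, and
with Δ = 0 the length effect vanishes once the block reaches steady
state.

## Design choices and limitations

- Measurement definition: the filter measures the imposed delay itself
  (0 during baseline); the state is adjustment relative to baseline, and
  predictions are compared to baseline-centred responses.
- Repository shape: the fitting surface follows the Model/Results
  convention (`AdaptationModel.fit()` → `AdaptationResults` with
  `summary()`); the filter, generator, statistics and paradigm layers are
  plain functions and dataclasses.
- Problem sizes: the acceptance script uses 200 (MC) and 100 (UC)
  recovery replicates, one 10-participant two-condition cohort, and
  2,000-resample bootstraps — sizes at which medians and orderings are
  stable while a full run stays under a minute.
- The single-rate filter cannot produce savings, anterograde
  interference, or a *persistent* asymptotic shortfall under a stationary
  perturbation (the gain never reaches zero, so it converges eventually);
  multi-rate learning and non-stationary process variance are out of
  scope. The washout-speed length effect it predicts is opposite to the
  empirical literature — a known property of this model class, not a bug.
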