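# Methods

## Model and conventions

Angles are degrees throughout and the exponential-quadratic loss uses raw
degree differences, `E(x; θ) = 1 − exp(−(x − (θ + b))²)`.  This makes the
loss well roughly as wide as the task's ~2° target region; it also means
the well is *narrow* relative to both the equilibrium support (180° by
default) and the per-trial rotation steps (5–10°), which drives most of the
finite-sample phenomenology discussed below.

The free energy is implemented as `F = −(1/β) log ∫_A exp(−βE) dx`.  The
sign is forced by normalization: only with the negative sign does
`exp(−β(E − F))` integrate to one over the support.  (ΔF is zero for every
analysis in this package because each protocol segment starts and ends in
the same environment, so the sign choice never touches a reported number.)

β = 0 is rejected at model construction; the purely stochastic limit is a
truncated uniform, which is its own model, not a limiting case of the
quadrature-based code path.

The inverted Mexican-hat control loss is an inverted Ricker wavelet,
`E = (1 − u²/σ²) exp(−u²/(2σ²))`, σ = 4° by default — maximal (worst) at
the target, so it assigns low utility exactly where the adapted response
sits.  Energy forms live in a registry (`register_energy_form`), so an
alternative analytic form can replace it without touching the pipeline.

## Protocol

One cycle is 66 trials: a 25-trial forward segment tracing a triangular
excursion 0 → +θ_peak → −θ_peak → 0 (breakpoints at trials 1, 7, 19, 25),
an 8-trial washout plateau at θ = 0, the 25-trial backward segment (the
forward angles reversed), and a second 8-trial plateau.  The default run is
100 baseline trials plus 20 cycles.  Every segment length, the excursion
shape, and θ_peak are configurable.

θ_peak defaults to 60°.  The driving-error spread this produces matches the
regime the analysis is designed for: per-cycle |ΔE_ext| fills the range up
to about 4 and essentially every segment interacts with the loss well.  At
smaller peaks (≤30°) the ±θ_peak sweep misses any response outside
±(θ_peak + 3°), so roughly half of all segments carry exactly zero driving
error; the resulting atom at w = 0 makes kernel density ratios severely
biased.  With the 60° default the zero-atom fraction drops to ~10%.

## The synthetic learner

The generator is a Metropolis–Hastings chain over response angles: a
symmetric Gaussian random-walk proposal (scale 10°), proposals outside the
support rejected, acceptance `min(1, exp(−β ΔE))`, 3 transitions per trial,
initialized from the equilibrium of the first trial.  This satisfies the
fluctuation theorems' premises *exactly* (Markov; equilibrium start;
per-trial detailed balance), which is what makes it a valid positive
control for the estimators.  The number of transitions per trial and the
proposal scale are free parameters of the learner, not measured
quantities.

What the generator emulates: Markov trial-to-trial dependence, per-trial
Boltzmann equilibria, re-equilibration during washouts, and (at many steps
per trial) graded adaptation levels.  What it does not emulate: human motor
noise of several degrees around a partially adapted mean.  A real
participant adapted "50%" to a 30° rotation responds near 15° ± 7° and is
almost never inside the 1°-wide loss well, so their per-segment driving
errors stay moderate while their fitted β is small and their
exponentiated-work intervals are very wide.  An MH learner can only adapt
by *occupying* the well; once it does, every 5–10° rotation step charges it
nearly one full energy unit, so a strongly adapted chain dissipates
w ≈ +20 per forward segment and its 20-sample exponentiated-work average
collapses toward zero.  Passing tests on the simulated cohort therefore
show that the estimators behave correctly for a learner that satisfies the
premises; they do not show that every qualitative pattern seen in human
cohorts (in particular, Jarzynski consistency *together with* ≥50%
adaptation) is reachable by this learner class.

Cohorts: the "well-adapted" cohort used for the control analyses draws
β ∈ [6, 9] and b ∈ [−3, 3] per participant, support `[b − 45, b + 45]`,
θ_peak = 30, 300 transitions per trial (near per-trial equilibration;
adaptation fractions 0.83–0.98).  The hysteresis demonstration instead uses
a laggier learner (proposal 5°, 40 transitions per trial), because visible
hysteresis requires incomplete per-trial equilibration.

## Estimators

Work extraction uses transitions strictly inside each segment (the
preceding plateau-to-segment transition carries θ = 0 → 0 and would be zero
under the default shapes anyway); one forward and one backward value per
cycle.

Densities ρ_F, ρ_B are Gaussian-kernel KDEs with Silverman's rule
(`std · (3n/4)^{−1/5}`, the scipy `gaussian_kde` convention); a fixed
bandwidth can be forced.  Before log-ratios, densities are floored at
1e−12 and floored grid points are flagged.  The Crooks curve additionally
reports a `reliable` mask — both full-sample densities ≥ 0.01 per unit work
— because the variance of a log-KDE ratio grows like the inverse density;
points outside that region are kernel-tail artifacts.  The summary line fit
(`CrooksCurve.linear_fit`) is weighted least squares with weights
`1/(1/ρ_F + 1/ρ_B)`, the leading-order inverse variance.

Bootstrap: percentile method, resample size = original size, forward and
backward sample sets resampled independently, 1000 replicates and a 99%
level by default; the curve reported is the mean bootstrap path with the
pointwise percentile band.  Whether forward/backward should instead be
resampled jointly per cycle is undecidable from the published description;
independent resampling is used and recorded in output metadata.
Known limitation: for n = 20 cycles the percentile CI of the right-skewed
mean `exp(−βw)` undercovers (measured ~0.89 true coverage at nominal 0.99
across replicate simulations, with every miss an interval entirely below
1 — small samples lack the rare negative-work realizations), and the KDE
smoothing bias at n = 20 narrows the Crooks band near the bulk.  These are
properties of the estimators at this sample size, not of the learner.

## Participant fitting

From the 100-trial baseline: `b̂` is the baseline mean; the support
defaults to `[b̂ − 90, b̂ + 90]` (a data-driven min/max ± 5° option
exists); `β̂` maximizes the truncated-equilibrium log-likelihood by bounded
scalar search on [0.01, 100], with a flag when the optimum pins at a bound
(zero-variance data pin high; flat data pin low).  This reconstruction is
isolated in one operation so a different fitting protocol can replace it.
Caveat: for sharply peaked equilibria (β ≳ 5) a handful of flat-region
outliers shift the baseline mean by ~1°, several well widths, so
single-run equilibration KS checks against such fits are noisy; the KS
check is a diagnostic (default threshold 0.1), not an inferential test, and
the equilibration premise itself is verified on pooled plateau trials
(KS < 0.05 at ≥10,000 pooled responses across independent runs).

## Numerical choices

Quadrature for log Z: adaptive `quad` on the support with a breakpoint at
θ + b, absolute tolerance 1e−9, failure raised with diagnostics.
Equilibrium CDF/sampling: trapezoid accumulation on a 4096-point grid, half
uniform over the support and half concentrated within the energy form's
structured window around θ + b (±8° for the exponential-quadratic, ±5σ for
the Mexican hat), inverse-CDF sampling by interpolation.  Chain simulation
pre-draws all proposal and acceptance variates from one seeded generator
per run, so every trajectory is reproducible from its integer seed; the
pipeline derives all stage seeds from one root seed and logs them.

## Problem sizes

Default analyses use the experimental scale (20 cycles, 1000 bootstrap
replicates); long-run convergence checks use 1000 cycles; replicate studies
in the test suite use 100–200 independent runs; oracle comparisons use
exact enumeration on a 3-state chain plus 1e5 sampled paths.
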