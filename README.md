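# fluctlearn

Fluctuation-theorem analysis of trial-by-trial sensorimotor adaptation.

When people adapt to a visuomotor rotation — the cursor on the screen is
rotated by an angle θ relative to the true hand movement — their pointing
responses `x` can be modelled as a Markov chain relaxing toward a Boltzmann
equilibrium of a sensorimotor loss.  `fluctlearn` turns that picture into a
tested analysis pipeline for trial-level adaptation data, aimed at
researchers in motor control and computational neuroscience who want to ask
whether adaptive behavior obeys the nonequilibrium relations known from
stochastic thermodynamics.

## The model

Each trial `n` imposes a rotation θₙ; a response `x` incurs the
exponential-quadratic loss (angles in degrees)

    E_n(x) = 1 − exp(−(x − (θ_n + b))²),

with participant-specific bias `b`.  A bounded-rational learner with
precision β settles into the truncated Boltzmann equilibrium on a support
`A = [lo, hi]`,

    p_eq(x) = exp(−β (E_n(x) − F_n)),   F_n = −(1/β) log ∫_A exp(−β E_n) dx.

Along a trajectory `x₀ … x_N` the cumulative loss change splits exactly into
a driving (work-like) part charged by the environment and an adaptation
(heat-like) part:

    ΔE_ext = Σ E_{n+1}(x_n) − E_n(x_n),     ΔE_int = Σ E_n(x_n) − E_n(x_{n−1}).

For a cyclic protocol whose backward half replays the forward rotation
sequence in reverse (so ΔF = 0), the per-cycle driving errors obey Crooks'
fluctuation theorem and Jarzynski's equality

    (1/β) log [ρ_F(w) / ρ_B(−w)] = w − ΔF,      ⟨e^{−β ΔE_ext}⟩ = e^{−β ΔF} = 1,

which the package tests with Gaussian-kernel density estimates of ρ_F, ρ_B
and percentile-bootstrap inference.  Since no participant-level data set is
publicly deposited for this task, a Metropolis–Hastings learner that
satisfies the theorems' premises exactly (Markov transitions in detailed
balance with each trial's equilibrium, equilibrium initialization) serves as
the synthetic-data generator.

## Worked example

```python
import numpy as np
from fluctlearn import (EnergyModel, LearnerConfig, build_protocol, simulate_run,
                        extract_work_samples, jarzynski, crooks_curve, free_energy)

model = EnergyModel(kind="exp_quad", beta=1.0, bias=0.0, support=(-90.0, 90.0))
print("free energy at theta=0:", round(free_energy(model, 0.0), 4))

protocol = build_protocol(n_cycles=1000)          # 100 baseline + 1000 x 66 trials
traj = simulate_run(model, protocol, LearnerConfig(), seed=0)
work = extract_work_samples(model, protocol, traj)
print("forward samples:", work.forward.size, " mean exp(-w):",
      round(float(np.exp(-work.forward).mean()), 4))

curve = crooks_curve(work, beta=1.0, n_boot=1, seed=0)
slope, intercept = curve.linear_fit()
print("Crooks line: slope=%.3f intercept=%.3f" % (slope, intercept))

short = build_protocol()                          # the experimental 20-cycle scale
traj20 = simulate_run(model, short, LearnerConfig(), seed=0)
res = jarzynski(extract_work_samples(model, short, traj20),
                beta=1.0, n_boot=1000, level=0.99, seed=0)
print("20-cycle Jarzynski: point=%.3f CI=(%.3f, %.3f) consistent=%s"
      % (res.point_estimate, res.ci_low, res.ci_high, res.consistent))
```

prints

```
free energy at theta=0: -4.2074
forward samples: 1000  mean exp(-w): 1.0055
Crooks line: slope=0.999 intercept=-0.053
20-cycle Jarzynski: point=1.437 CI=(0.759, 2.882) consistent=True
```

The long run recovers the parameter-free prediction ⟨e^{−ΔE_ext}⟩ = 1 to
half a percent and a unit-slope log-density-ratio line; at the experimental
scale of 20 cycles the bootstrap interval is wide but still brackets 1,
i.e. the data are consistent with perfect thermodynamic adaptation.

The command line mirrors the library (`fluctlearn simulate | fit | work |
crooks | jarzynski | hysteresis | controls | pipeline`), driven by one YAML
config with sections `energy`, `protocol`, `learner`, `cohort`,
`estimators`, `controls`:

```sh
fluctlearn pipeline --seed 1 --out-dir out/
```

writes the simulated trial table, per-participant fits, work samples,
Crooks curves, Jarzynski intervals, hysteresis/adaptation summaries, the
two negative controls (inverted Mexican-hat loss, randomized resampling),
and a report with every seed used.

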