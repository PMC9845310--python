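"""Metropolis-Hastings learner driven through a rotation protocol.

The synthetic stand-in for a human participant is a Markov chain over
response angles whose per-trial target is the Boltzmann equilibrium of the
current rotation: a symmetric Gaussian random-walk proposal, rejection of
proposals outside the support, and Metropolis acceptance
``min(1, exp(-beta * dE))``.  The transition kernel satisfies detailed
balance with respect to the truncated equilibrium at every trial, and the
chain is initialized from the equilibrium of the first trial, which are
exactly the premises of the fluctuation theorems tested downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel, sample_equilibrium, scalar_energy
from .errors import InvalidInputError, InvalidStateError
from .protocol import Protocol

__all__ = [
    "LearnerConfig",
    "Trajectory",
    "metropolis_acceptance",
    "mh_step",
    "simulate_run",
    "simulate_cohort",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Sampler settings for the simulated learner.

    proposal_scale : standard deviation of the Gaussian random-walk
        proposal in degrees.
    steps_per_trial : Metropolis-Hastings transitions applied per trial;
        the recorded response is the state after the last one.
    init : ``"equilibrium"`` draws the initial state from the equilibrium
        of the first trial; ``"fixed"`` starts at the target of the first
        trial (clipped to the support).
    """

    proposal_scale: float = 10.0
    steps_per_trial: int = 3
    init: str = "equilibrium"

    def __post_init__(self):
        if not (np.isfinite(self.proposal_scale) and self.proposal_scale > 0):
            raise InvalidInputError("proposal_scale must be finite and > 0")
        if self.steps_per_trial < 1:
            raise InvalidInputError("steps_per_trial must be >= 1")
        if self.init not in ("equilibrium", "fixed"):
            raise InvalidInputError("init must be 'equilibrium' or 'fixed'")


@dataclass
class Trajectory:
    """Response angles aligned to a protocol, one per trial."""

    responses: np.ndarray
    source: str = "simulated"
    participant_id: str = "sim"
    seed: int | None = None

    def __post_init__(self):
        r = np.asarray(self.responses, dtype=float)
        if r.ndim != 1 or not np.all(np.isfinite(r)):
            raise InvalidInputError("responses must be a finite 1-D sequence")
        self.responses = r

    def __len__(self) -> int:
        return self.responses.size


def metropolis_acceptance(model: EnergyModel, theta: float, x_from: float, x_to: float) -> float:
    """Acceptance probability of the move ``x_from -> x_to`` at ``theta``.

    Zero for proposals outside the support; otherwise
    ``min(1, exp(-beta * (E(x_to) - E(x_from))))``.
    """
    lo, hi = model.support
    if not lo <= x_to <= hi:
        return 0.0
    energy = scalar_energy(model)
    d_e = energy(x_to, theta) - energy(x_from, theta)
    if d_e <= 0:
        return 1.0
    return math.exp(-model.beta * d_e)


def mh_step(model, theta, x, cfg: LearnerConfig, rng, proposal=None):
    """One Metropolis-Hastings transition from state ``x`` at angle ``theta``.

    ``proposal`` forces a specific proposed state (used for testing the
    acceptance rule); by default a Gaussian perturbation of scale
    ``cfg.proposal_scale`` is drawn from ``rng``.
    """
    lo, hi = model.support
    if not (np.isfinite(x) and lo <= x <= hi):
        raise InvalidStateError(f"state {x!r} outside support {model.support}")
    if proposal is None:
        proposal = x + cfg.proposal_scale * rng.standard_normal()
    a = metropolis_acceptance(model, theta, x, proposal)
    if a >= 1.0 or rng.random() < a:
        return float(proposal)
    return float(x)


def _run_chain(model, thetas, x0, cfg: LearnerConfig, rng) -> np.ndarray:
    """Drive the chain through ``thetas``, recording one state per trial."""
    thetas = [float(t) for t in thetas]
    n = len(thetas)
    steps = cfg.steps_per_trial
    noise = (cfg.proposal_scale * rng.standard_normal(n * steps)).tolist()
    logu = np.log(rng.random(n * steps)).tolist()
    lo, hi = model.support
    beta = model.beta
    energy = scalar_energy(model)
    out = np.empty(n)
    x = float(x0)
    k = 0
    for i in range(n):
        th = thetas[i]
        ex = energy(x, th)
        for _ in range(steps):
            xp = x + noise[k]
            if lo <= xp <= hi:
                ep = energy(xp, th)
                if ep <= ex or logu[k] < -beta * (ep - ex):
                    x = xp
                    ex = ep
            k += 1
        out[i] = x
    return out


def simulate_run(
    model: EnergyModel,
    protocol: Protocol,
    cfg: LearnerConfig | None = None,
    seed=None,
    participant_id: str = "sim",
) -> Trajectory:
    """Simulate one learner through the full protocol (baseline + cycles).

    The initial state is an equilibrium draw for the first trial's angle
    (or the clipped target when ``cfg.init == "fixed"``); each trial applies
    ``cfg.steps_per_trial`` transitions under that trial's angle and records
    the final state.  Fully reproducible for a fixed integer seed.
    """
    cfg = cfg or LearnerConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thetas = protocol.thetas
    if cfg.init == "equilibrium":
        x0 = sample_equilibrium(model, float(thetas[0]), 1, rng)[0]
    else:
        lo, hi = model.support
        x0 = float(np.clip(thetas[0] + model.bias, lo, hi))
    responses = _run_chain(model, thetas, x0, cfg, rng)
    return Trajectory(
        responses=responses,
        source="simulated",
        participant_id=participant_id,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def simulate_cohort(
    protocol: Protocol,
    cfg: LearnerConfig | None = None,
    n_participants: int = 10,
    beta_range: tuple[float, float] = (6.0, 9.0),
    bias_range: tuple[float, float] = (-3.0, 3.0),
    support_halfwidth: float = 90.0,
    seed=None,
):
    """Simulate a cohort of learners with participant-specific (beta, b).

    Each participant's precision and bias are drawn uniformly from the
    given ranges and its support is ``[b - hw, b + hw]``.  Returns a list of
    ``(participant_id, EnergyModel, Trajectory)`` triples.
    """
    if n_participants < 1:
        raise InvalidInputError("n_participants must be >= 1")
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    runs = []
    for i, child in enumerate(ss.spawn(n_participants + 1)[1:], start=1):
        beta = draw_rng.uniform(*beta_range)
        bias = draw_rng.uniform(*bias_range)
        model = EnergyModel(
            kind="exp_quad",
            beta=beta,
            bias=bias,
            support=(bias - support_halfwidth, bias + support_halfwidth),
        )
        pid = f"S{i:02d}"
        traj = simulate_run(
            model, protocol, cfg, seed=np.random.default_rng(child), participant_id=pid
        )
        runs.append((pid, model, traj))
    return runs
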