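"""Shared fixtures and the exactly-solvable discrete-chain oracle."""

from __future__ import annotations

import numpy as np
import pytest

from fluctlearn import (
    EnergyModel,
    LearnerConfig,
    build_protocol,
    extract_work_samples,
    simulate_run,
)

# ---------------------------------------------------------------------------
# Three-state discrete-chain toy with one environment switch.
#
# Two environments assign energies E1 = (0, 0.5, 1) and E2 = (1, 0.5, 0) to
# three states.  A path starts in the Boltzmann equilibrium of the first
# environment, the environment switches (charging the driving error
# w = E2(x0) - E1(x0)), and one detailed-balance transition under the new
# environment follows.  Every path probability can be enumerated, so the
# log-ratio identity can be checked without any density estimation.
# ---------------------------------------------------------------------------

TOY_E1 = np.array([0.0, 0.5, 1.0])
TOY_E2 = np.array([1.0, 0.5, 0.0])
TOY_BETA = 1.0


def toy_equilibrium(energies, beta=TOY_BETA):
    w = np.exp(-beta * energies)
    return w / w.sum()


def toy_kernel(energies, beta=TOY_BETA):
    """Discrete Metropolis kernel, uniform proposal over the three states."""
    n = energies.size
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                T[i, j] = (1.0 / n) * min(1.0, np.exp(-beta * (energies[j] - energies[i])))
        T[i, i] = 1.0 - T[i].sum()
    return T


def toy_enumerate(direction="forward"):
    """Exact work distribution by summing over all two-trial paths."""
    e_first, e_second = (TOY_E1, TOY_E2) if direction == "forward" else (TOY_E2, TOY_E1)
    p0 = toy_equilibrium(e_first)
    T = toy_kernel(e_second)
    dist: dict[float, float] = {}
    for x0 in range(3):
        w = float(e_second[x0] - e_first[x0])
        for x1 in range(3):
            dist[w] = dist.get(w, 0.0) + p0[x0] * T[x0, x1]
    return dist


def toy_sample(n, direction="forward", seed=0):
    """Sample n two-trial paths and return their driving-error values."""
    rng = np.random.default_rng(seed)
    e_first, e_second = (TOY_E1, TOY_E2) if direction == "forward" else (TOY_E2, TOY_E1)
    p0 = toy_equilibrium(e_first)
    T = toy_kernel(e_second)
    x0 = rng.choice(3, size=n, p=p0)
    u = rng.random(n)
    cum = np.cumsum(T, axis=1)
    _x1 = (u[:, None] < cum[x0]).argmax(axis=1)  # transition drawn but w ignores it
    return e_second[x0] - e_first[x0]


# ---------------------------------------------------------------------------
# Shared simulation fixtures (session-scoped; the long run is reused by the
# acceptance checks for the exponentiated-work average and the log-ratio
# linearity).
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_model():
    return EnergyModel(kind="exp_quad", beta=1.0, bias=0.0, support=(-90.0, 90.0))


@pytest.fixture(scope="session")
def default_protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def long_run_work(default_model):
    protocol = build_protocol(n_cycles=1000)
    traj = simulate_run(default_model, protocol, LearnerConfig(), seed=0)
    return extract_work_samples(default_model, protocol, traj)


@pytest.fixture(scope="session")
def short_run_work(default_model, default_protocol):
    traj = simulate_run(default_model, default_protocol, LearnerConfig(), seed=0)
    return extract_work_samples(default_model, default_protocol, traj)
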