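"""Driving-error ("work") and adaptation ("heat") decomposition.

Along a trajectory of responses ``x_n`` under rotations ``theta_n`` the
cumulative energy change splits exactly into an externally driven part,
charged when the environment switches while the response is held,

    dE_ext = sum_{n=0}^{N-1}  E(x_n; theta_{n+1}) - E(x_n; theta_n),

and an internal part, accrued when the learner moves under a fixed
environment,

    dE_int = sum_{n=1}^{N}    E(x_n; theta_n) - E(x_{n-1}; theta_n).

Their sum telescopes to ``E(x_N; theta_N) - E(x_0; theta_0)`` (first law).
``dE_ext`` is the work analog entering the fluctuation theorems; one value
is extracted per cycle for the forward and the backward segment, using only
transitions strictly inside the segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import EnergyModel, evaluate_energy
from .errors import InvalidInputError
from .protocol import Protocol
from .simulate import Trajectory

__all__ = ["WorkSamples", "external_work", "internal_heat", "extract_work_samples"]


@dataclass
class WorkSamples:
    """Per-cycle driving-error samples for both protocol directions."""

    forward: np.ndarray
    backward: np.ndarray
    participant_id: str = ""
    model: EnergyModel | None = None

    def __post_init__(self):
        f = np.asarray(self.forward, dtype=float)
        b = np.asarray(self.backward, dtype=float)
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(b))):
            raise InvalidInputError("work samples must be finite")
        self.forward, self.backward = f, b

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: participant_id, cycle, direction, delta_E_ext."""
        rows = []
        for direction, vals in (("F", self.forward), ("B", self.backward)):
            for cycle, v in enumerate(vals, start=1):
                rows.append((self.participant_id, cycle, direction, v))
        return pd.DataFrame(rows, columns=["participant_id", "cycle", "direction", "delta_E_ext"])


def _check_pair(thetas, xs):
    thetas = np.asarray(thetas, dtype=float)
    xs = np.asarray(xs, dtype=float)
    if thetas.shape != xs.shape or thetas.ndim != 1:
        raise InvalidInputError("thetas and xs must be 1-D of equal length")
    if thetas.size < 2:
        raise InvalidInputError("need at least 2 trials")
    if not (np.all(np.isfinite(thetas)) and np.all(np.isfinite(xs))):
        raise InvalidInputError("thetas and xs must be finite")
    return thetas, xs


def external_work(model: EnergyModel, thetas, xs) -> float:
    """Externally driven energy change along one segment."""
    thetas, xs = _check_pair(thetas, xs)
    e_next = evaluate_energy(model, xs[:-1], thetas[1:])
    e_curr = evaluate_energy(model, xs[:-1], thetas[:-1])
    return float(np.sum(e_next - e_curr))


def internal_heat(model: EnergyModel, thetas, xs) -> float:
    """Internally generated energy change along one segment."""
    thetas, xs = _check_pair(thetas, xs)
    e_new = evaluate_energy(model, xs[1:], thetas[1:])
    e_old = evaluate_energy(model, xs[:-1], thetas[1:])
    return float(np.sum(e_new - e_old))


def extract_work_samples(
    model: EnergyModel, protocol: Protocol, trajectory: Trajectory
) -> WorkSamples:
    """One forward and one backward driving-error value per cycle.

    The trajectory must be aligned to the protocol (one response per
    protocol trial, baseline included).
    """
    xs = trajectory.responses
    if xs.size != protocol.n_trials:
        raise InvalidInputError(
            f"trajectory length {xs.size} does not match protocol length {protocol.n_trials}"
        )
    thetas = protocol.thetas
    fwd = np.empty(protocol.n_cycles)
    bwd = np.empty(protocol.n_cycles)
    for c in range(1, protocol.n_cycles + 1):
        fi = protocol.forward_indices(c)
        bi = protocol.backward_indices(c)
        fwd[c - 1] = external_work(model, thetas[fi], xs[fi])
        bwd[c - 1] = external_work(model, thetas[bi], xs[bi])
    return WorkSamples(fwd, bwd, participant_id=trajectory.participant_id, model=model)
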