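"""Cyclic forward/backward rotation protocols.

A protocol is a deterministic sequence of imposed rotation angles
``theta_n``: an unperturbed baseline block followed by ``n_cycles``
repetitions of one cycle.  Within a cycle the forward segment traces an
excursion away from zero and back, a washout plateau holds ``theta = 0``,
the backward segment replays the forward angles in reversed order, and a
second plateau closes the cycle.  Because every realization starts and ends
in the same environment, the free-energy difference across a segment is
zero, which is what makes the exponentiated-work average a parameter-free
prediction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidInputError

__all__ = ["Protocol", "build_protocol"]


@dataclass(frozen=True)
class Protocol:
    """One cycle of rotation angles plus block structure.

    Attributes
    ----------
    cycle_angles : tuple of float
        Imposed angles ``theta`` (degrees) for one cycle.
    n_cycles : int
        Number of cycle repetitions after the baseline block.
    forward_range, backward_range : (int, int)
        Inclusive 1-based trial ranges of the forward and backward
        segments within a cycle.  The backward angles must equal the
        reversed forward angles.
    baseline_length : int
        Number of unperturbed (``theta = 0``) trials preceding cycle 1.
    """

    cycle_angles: tuple[float, ...]
    n_cycles: int
    forward_range: tuple[int, int]
    backward_range: tuple[int, int]
    baseline_length: int

    def __post_init__(self):
        angles = np.asarray(self.cycle_angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0 or not np.all(np.isfinite(angles)):
            raise ConfigError("cycle_angles must be a non-empty finite 1-D sequence")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.baseline_length < 0:
            raise ConfigError("baseline_length must be >= 0")
        f_lo, f_hi = self.forward_range
        b_lo, b_hi = self.backward_range
        L = angles.size
        for lo, hi, name in [(f_lo, f_hi, "forward"), (b_lo, b_hi, "backward")]:
            if not (1 <= lo <= hi <= L):
                raise ConfigError(f"{name}_range {lo, hi} outside cycle of length {L}")
        if f_hi - f_lo != b_hi - b_lo:
            raise ConfigError("forward and backward segments must have equal length")
        if f_hi >= b_lo:
            raise ConfigError("forward segment must precede the backward segment")
        fwd = angles[f_lo - 1 : f_hi]
        bwd = angles[b_lo - 1 : b_hi]
        if not np.array_equal(bwd, fwd[::-1]):
            raise ConfigError("backward angles must be the reversed forward angles")
        outside = np.ones(L, dtype=bool)
        outside[f_lo - 1 : f_hi] = False
        outside[b_lo - 1 : b_hi] = False
        if np.any(angles[outside] != 0.0):
            raise ConfigError("washout trials outside the segments must have theta = 0")
        object.__setattr__(self, "cycle_angles", tuple(float(a) for a in angles))

    @property
    def cycle_length(self) -> int:
        return len(self.cycle_angles)

    @property
    def segment_length(self) -> int:
        return self.forward_range[1] - self.forward_range[0] + 1

    @property
    def n_trials(self) -> int:
        return self.baseline_length + self.n_cycles * self.cycle_length

    @property
    def thetas(self) -> np.ndarray:
        """Full angle sequence: baseline zeros then tiled cycles."""
        return np.concatenate(
            [np.zeros(self.baseline_length), np.tile(self.cycle_angles, self.n_cycles)]
        )

    def _segment_indices(self, cycle: int, rng: tuple[int, int]) -> np.ndarray:
        if not 1 <= cycle <= self.n_cycles:
            raise InvalidInputError(f"cycle {cycle} outside 1..{self.n_cycles}")
        start = self.baseline_length + (cycle - 1) * self.cycle_length
        return np.arange(start + rng[0] - 1, start + rng[1])

    def forward_indices(self, cycle: int) -> np.ndarray:
        """Global 0-based trial indices of the forward segment of ``cycle``."""
        return self._segment_indices(cycle, self.forward_range)

    def backward_indices(self, cycle: int) -> np.ndarray:
        """Global 0-based trial indices of the backward segment of ``cycle``."""
        return self._segment_indices(cycle, self.backward_range)

    def plateau_mask(self) -> np.ndarray:
        """Boolean mask over main-block trials of washout-plateau positions."""
        in_cycle = np.ones(self.cycle_length, dtype=bool)
        f_lo, f_hi = self.forward_range
        b_lo, b_hi = self.backward_range
        in_cycle[f_lo - 1 : f_hi] = False
        in_cycle[b_lo - 1 : b_hi] = False
        return np.concatenate(
            [np.zeros(self.baseline_length, dtype=bool), np.tile(in_cycle, self.n_cycles)]
        )


def _triangular_forward(length: int, theta_peak: float) -> np.ndarray:
    """Triangular excursion 0 -> +peak -> -peak -> 0 over ``length`` trials."""
    if length < 4:
        raise ConfigError("forward segment needs at least 4 trials")
    j = np.arange(1, length + 1, dtype=float)
    q1 = 1 + round((length - 1) / 4)
    q3 = 1 + round(3 * (length - 1) / 4)
    return np.interp(j, [1, q1, q3, length], [0.0, theta_peak, -theta_peak, 0.0])


def build_protocol(
    theta_peak: float = 60.0,
    forward_length: int = 25,
    plateau_length: int = 8,
    n_cycles: int = 20,
    baseline_length: int = 100,
    forward_angles=None,
) -> Protocol:
    """Build the default cyclic protocol.

    Per cycle: a ``forward_length``-trial excursion 0 -> +peak -> -peak -> 0,
    a washout plateau, the reversed excursion, and a second plateau
    (25 + 8 + 25 + 8 = 66 trials with the defaults).  ``forward_angles``
    overrides the triangular shape with an explicit sequence.
    """
    if forward_angles is None:
        if not np.isfinite(theta_peak) or theta_peak < 0:
            raise ConfigError("theta_peak must be finite and >= 0")
        fwd = _triangular_forward(forward_length, float(theta_peak))
    else:
        fwd = np.asarray(forward_angles, dtype=float)
        if fwd.ndim != 1 or not np.all(np.isfinite(fwd)):
            raise ConfigError("forward_angles must be a finite 1-D sequence")
    if plateau_length < 0:
        raise ConfigError("plateau_length must be >= 0")
    L = fwd.size
    cycle = np.concatenate([fwd, np.zeros(plateau_length), fwd[::-1], np.zeros(plateau_length)])
    return Protocol(
        cycle_angles=tuple(cycle),
        n_cycles=n_cycles,
        forward_range=(1, L),
        backward_range=(L + plateau_length + 1, 2 * L + plateau_length),
        baseline_length=baseline_length,
    )
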