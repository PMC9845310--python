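"""Sensorimotor loss functions and their truncated Boltzmann equilibria.

A pointing response at angle ``x`` (degrees) under an imposed visuomotor
rotation ``theta`` (degrees) incurs a dimensionless loss ("energy")

* ``exp_quad``:     ``E(x; theta) = 1 - exp(-(x - (theta + b))**2)``
* ``mexican_hat``:  inverted Ricker wavelet, maximal (worst) at the target:
  ``E(x; theta) = (1 - u**2/sigma**2) * exp(-u**2 / (2 sigma**2))`` with
  ``u = x - (theta + b)``.

``b`` is a participant-specific bias in degrees.  A bounded-rational learner
with precision ``beta`` settles into the truncated Boltzmann equilibrium

    p_eq(x) = exp(-beta * (E(x; theta) - F(theta)))       for x in [lo, hi],

where the free energy ``F = -(1/beta) * log Z``,
``Z = \\int_lo^hi exp(-beta E) dx``, makes p_eq integrate to one.  Angle
differences enter the exponent as raw degrees (the target region of the task
is about 2 degrees wide, the same scale as the loss well).

Additional energy forms can be registered with :func:`register_energy_form`;
the registry is what lets a configured callable replace the Mexican-hat
stand-in without touching the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad

from .errors import InvalidInputError, NumericalError

__all__ = [
    "EnergyModel",
    "register_energy_form",
    "evaluate_energy",
    "scalar_energy",
    "free_energy",
    "equilibrium_pdf",
    "equilibrium_cdf",
    "sample_equilibrium",
]

# Each form maps (offset u = x - theta - bias, model) -> energy, vectorized.
_ENERGY_FORMS: dict[str, Callable[[np.ndarray, "EnergyModel"], np.ndarray]] = {}

# Half-width (degrees) of the structured region around theta + bias, used to
# refine quadrature/sampling grids.  Callables may override via registry entry.
_FORM_WINDOW: dict[str, Callable[["EnergyModel"], float]] = {}


def register_energy_form(name, fn, window=None):
    """Register an energy form ``fn(u, model) -> energy`` under ``name``.

    ``window(model)`` optionally returns the half-width in degrees of the
    region around ``theta + bias`` where the energy varies appreciably
    (used to refine integration grids).
    """
    _ENERGY_FORMS[name] = fn
    if window is not None:
        _FORM_WINDOW[name] = window


register_energy_form("exp_quad", lambda u, m: 1.0 - np.exp(-(u * u)), window=lambda m: 8.0)
register_energy_form(
    "mexican_hat",
    lambda u, m: (1.0 - (u / m.sigma) ** 2) * np.exp(-(u * u) / (2.0 * m.sigma**2)),
    window=lambda m: 5.0 * m.sigma,
)


@dataclass(frozen=True)
class EnergyModel:
    """Parametric sensorimotor loss with its Boltzmann equilibrium.

    Parameters
    ----------
    kind : str
        Registered energy form, ``"exp_quad"`` or ``"mexican_hat"``.
    beta : float
        Inverse temperature (precision), dimensionless, strictly positive.
        ``beta = 0`` (purely stochastic responding) is rejected: the
        truncated uniform is its own model, not a limit taken here.
    bias : float
        Participant-specific bias ``b`` in degrees.
    support : tuple of float
        Closed interval ``[lo, hi]`` (degrees) carrying the equilibrium.
    sigma : float
        Width in degrees of the Mexican-hat form; ignored otherwise.
    """

    kind: str = "exp_quad"
    beta: float = 1.0
    bias: float = 0.0
    support: tuple[float, float] = (-90.0, 90.0)
    sigma: float = 4.0

    def __post_init__(self):
        if self.kind not in _ENERGY_FORMS:
            raise InvalidInputError(f"unknown energy kind {self.kind!r}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise InvalidInputError(
                "beta must be finite and > 0 (use a uniform model for the "
                "purely stochastic limit)"
            )
        lo, hi = self.support
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise InvalidInputError("support must be a finite interval with lo < hi")
        if not np.isfinite(self.bias):
            raise InvalidInputError("bias must be finite")
        if self.kind == "mexican_hat" and not (np.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidInputError("sigma must be finite and > 0 for mexican_hat")
        object.__setattr__(self, "support", (float(lo), float(hi)))

    def in_support(self, x) -> np.ndarray:
        lo, hi = self.support
        return (np.asarray(x) >= lo) & (np.asarray(x) <= hi)


def evaluate_energy(model: EnergyModel, x, theta):
    """Loss of response ``x`` under rotation ``theta``, both in degrees.

    Defined for any finite ``x`` (the support only truncates the
    equilibrium, not the loss).  Broadcasts over array inputs.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(theta))):
        raise InvalidInputError("x and theta must be finite")
    u = x - (theta + model.bias)
    out = _ENERGY_FORMS[model.kind](u, model)
    if out.ndim == 0:
        return float(out)
    return out


def scalar_energy(model: EnergyModel) -> Callable[[float, float], float]:
    """Return a fast scalar ``E(x, theta)`` closure for chain simulation."""
    b = model.bias
    if model.kind == "exp_quad":

        def energy(x, theta):
            d = x - theta - b
            return 1.0 - math.exp(-(d * d))

    elif model.kind == "mexican_hat":
        s2 = model.sigma**2

        def energy(x, theta):
            d = x - theta - b
            q = d * d / s2
            return (1.0 - q) * math.exp(-0.5 * q)

    else:
        form = _ENERGY_FORMS[model.kind]

        def energy(x, theta):
            return float(form(np.float64(x - theta - b), model))

    return energy


def _local_window(model: EnergyModel) -> float:
    fn = _FORM_WINDOW.get(model.kind)
    return fn(model) if fn is not None else 10.0


def log_partition(model: EnergyModel, theta: float) -> float:
    """``log Z`` with ``Z = \\int_support exp(-beta E(x; theta)) dx``."""
    theta = float(theta)
    if not np.isfinite(theta):
        raise InvalidInputError("theta must be finite")
    lo, hi = model.support
    beta = model.beta
    energy = scalar_energy(model)

    def integrand(x):
        return math.exp(-beta * energy(x, theta))

    center = theta + model.bias
    points = [center] if lo < center < hi else None
    val, abserr = quad(integrand, lo, hi, points=points, limit=200, epsabs=1e-9, epsrel=1e-10)
    if not np.isfinite(val) or val <= 0 or abserr > 1e-6 * max(abs(val), 1.0):
        raise NumericalError(
            f"partition-function quadrature failed: value={val!r}, abserr={abserr!r}, "
            f"theta={theta}, support={model.support}, beta={beta}"
        )
    return math.log(val)


def free_energy(model: EnergyModel, theta: float) -> float:
    """Free energy ``F(theta) = -(1/beta) log Z`` of the truncated equilibrium.

    The sign is fixed by normalization: with this convention
    ``exp(-beta (E - F))`` integrates to one over the support.
    """
    return -log_partition(model, theta) / model.beta


def equilibrium_pdf(model: EnergyModel, theta: float, x):
    """Equilibrium density (per degree) at ``x``; zero outside the support."""
    logZ = log_partition(model, theta)
    e = evaluate_energy(model, x, theta)
    dens = np.exp(-model.beta * np.asarray(e) - logZ)
    dens = np.where(model.in_support(x), dens, 0.0)
    if dens.ndim == 0:
        return float(dens)
    return dens


_N_GRID = 4096


def _support_grid(model: EnergyModel, theta: float) -> np.ndarray:
    """Support grid refined around the structured region of the loss."""
    lo, hi = model.support
    base = np.linspace(lo, hi, _N_GRID // 2)
    center = theta + model.bias
    w = _local_window(model)
    local = center + np.linspace(-w, w, _N_GRID // 2)
    local = local[(local > lo) & (local < hi)]
    extras = [np.clip(center, lo, hi)] if lo <= center <= hi else []
    return np.unique(np.concatenate([base, local, extras]))


def _grid_cdf(model: EnergyModel, theta: float):
    xs = _support_grid(model, theta)
    e = evaluate_energy(model, xs, theta)
    w = np.exp(-model.beta * (e - e.min()))
    c = cumulative_trapezoid(w, xs, initial=0.0)
    total = c[-1]
    if not np.isfinite(total) or total <= 0:
        raise NumericalError("equilibrium CDF grid integration failed")
    return xs, c / total


def equilibrium_cdf(model: EnergyModel, theta: float) -> Callable[[np.ndarray], np.ndarray]:
    """Return the equilibrium CDF as a callable built on a dense grid."""
    xs, c = _grid_cdf(model, theta)

    def cdf(x):
        return np.interp(np.asarray(x, dtype=float), xs, c, left=0.0, right=1.0)

    cdf.grid = xs
    cdf.values = c
    return cdf


def sample_equilibrium(model: EnergyModel, theta: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. responses from the equilibrium by inverse CDF.

    ``seed`` may be an int, a ``numpy.random.Generator``, or ``None``.
    Draws always lie within the support and are reproducible for a fixed
    integer seed.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, c = _grid_cdf(model, theta)
    u = rng.random(int(n))
    return np.interp(u, c, xs)
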