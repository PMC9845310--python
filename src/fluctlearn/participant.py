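"""Per-participant model fitting and the equilibration premise.

The fluctuation-theorem analysis needs, for every participant, a precision
``beta``, a bias ``b``, and an equilibrium support.  These are recovered
from the unperturbed baseline block (responses recorded at ``theta = 0``)
by maximum likelihood under the truncated Boltzmann equilibrium: the bias
is the baseline mean, the support defaults to ``[b - 90, b + 90]``
(the simulation support recentred on the bias; a data-driven min/max
option is provided), and ``beta`` maximizes the equilibrium log-likelihood
by bounded one-dimensional search.

The theorems further assume that behavior re-equilibrates during the
washout plateaus; ``equilibration_check`` quantifies this as the
Kolmogorov-Smirnov distance between the plateau responses and the fitted
equilibrium at ``theta = 0``.  The threshold is diagnostic, not an
inferential test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import ks_1samp

from .energy import EnergyModel, equilibrium_cdf, evaluate_energy, log_partition
from .errors import DegenerateDataError, InvalidInputError

__all__ = ["ParticipantFit", "EquilibrationReport", "fit_participant", "equilibration_check"]

_BETA_BOUNDS = (0.01, 100.0)


@dataclass
class ParticipantFit:
    """Maximum-likelihood equilibrium parameters from a baseline block."""

    beta_hat: float
    bias_hat: float
    support_hat: tuple[float, float]
    n_baseline: int
    loglik: float
    at_bound: str | None = None  # "lower" / "upper" when beta_hat is pinned

    def model(self, kind: str = "exp_quad", beta: float | None = None, **kw) -> EnergyModel:
        """Energy model with the fitted parameters (beta overridable)."""
        return EnergyModel(
            kind=kind,
            beta=self.beta_hat if beta is None else beta,
            bias=self.bias_hat,
            support=self.support_hat,
            **kw,
        )


@dataclass
class EquilibrationReport:
    """KS comparison of washout-plateau responses to the fitted equilibrium."""

    ks_distance: float
    n_plateau: int
    threshold: float
    passed: bool


def fit_participant(
    baseline_responses,
    support: tuple[float, float] | None = None,
    support_rule: str = "recentred",
    beta_bounds: tuple[float, float] = _BETA_BOUNDS,
    support_halfwidth: float = 90.0,
    support_pad: float = 5.0,
) -> ParticipantFit:
    """Fit (beta, b, support) from baseline responses recorded at theta = 0.

    ``support_rule``: ``"recentred"`` uses ``[b - hw, b + hw]``;
    ``"data"`` uses the response range padded by ``support_pad`` degrees.
    An explicit ``support`` overrides both.  The support is widened if
    necessary so that it contains every baseline response.
    """
    xs = np.asarray(baseline_responses, dtype=float)
    if xs.ndim != 1 or not np.all(np.isfinite(xs)):
        raise InvalidInputError("baseline responses must be a finite 1-D sequence")
    if xs.size < 10:
        raise DegenerateDataError("need at least 10 baseline trials")
    bias_hat = float(xs.mean())
    if support is None:
        if support_rule == "recentred":
            support = (bias_hat - support_halfwidth, bias_hat + support_halfwidth)
        elif support_rule == "data":
            support = (xs.min() - support_pad, xs.max() + support_pad)
        else:
            raise InvalidInputError(f"unknown support rule {support_rule!r}")
    eps = 1e-9
    support = (min(support[0], xs.min() - eps), max(support[1], xs.max() + eps))

    # log L(beta) = -beta * sum(E_i) - n * log Z(beta); E does not depend on beta.
    probe = EnergyModel(kind="exp_quad", beta=1.0, bias=bias_hat, support=support)
    sum_e = float(np.sum(evaluate_energy(probe, xs, 0.0)))
    n = xs.size

    def nll(beta):
        m = EnergyModel(kind="exp_quad", beta=beta, bias=bias_hat, support=support)
        return beta * sum_e + n * log_partition(m, 0.0)

    res = minimize_scalar(nll, bounds=beta_bounds, method="bounded", options={"xatol": 1e-5})
    beta_hat = float(res.x)
    lo_b, hi_b = beta_bounds
    span = hi_b - lo_b
    at_bound = None
    if beta_hat - lo_b < 1e-3 * span:
        at_bound, beta_hat = "lower", lo_b
    elif hi_b - beta_hat < 1e-3 * span:
        at_bound, beta_hat = "upper", hi_b
    return ParticipantFit(
        beta_hat=beta_hat,
        bias_hat=bias_hat,
        support_hat=(float(support[0]), float(support[1])),
        n_baseline=n,
        loglik=float(-nll(beta_hat)),
        at_bound=at_bound,
    )


def equilibration_check(
    plateau_responses, fit: ParticipantFit, threshold: float = 0.1
) -> EquilibrationReport:
    """KS distance of washout responses to the fitted equilibrium at theta=0."""
    xs = np.asarray(plateau_responses, dtype=float)
    if xs.ndim != 1 or not np.all(np.isfinite(xs)):
        raise InvalidInputError("plateau responses must be a finite 1-D sequence")
    if xs.size < 10:
        raise DegenerateDataError("need at least 10 plateau trials")
    cdf = equilibrium_cdf(fit.model(), 0.0)
    stat = float(ks_1samp(xs, cdf).statistic)
    return EquilibrationReport(
        ks_distance=stat, n_plateau=int(xs.size), threshold=float(threshold),
        passed=bool(stat < threshold),
    )
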