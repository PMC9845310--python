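"""Crooks and Jarzynski estimators with kernel densities and bootstrap.

Crooks' fluctuation theorem relates the densities of the driving error
``w = dE_ext`` under the forward and backward protocol,

    (1/beta) * log( rhoF(w) / rhoB(-w) ) = w - dF,

and Jarzynski's equality states ``< exp(-beta w) > = exp(-beta dF)`` over
forward realizations.  Both are estimated here from the per-cycle work
samples: Gaussian kernel density estimates (Silverman bandwidth by default)
for the log-density ratio, and percentile bootstrap for confidence bands
and intervals.  Densities are floored at a small positive constant before
logs; grid points where the floor was hit on the full-sample estimate are
flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidInputError
from .work import WorkSamples

__all__ = [
    "DensityEstimate",
    "CrooksCurve",
    "JarzynskiResult",
    "silverman_bandwidth",
    "fit_kde",
    "crooks_curve",
    "jarzynski",
]

DENSITY_FLOOR = 1e-12
_SQRT2PI = np.sqrt(2.0 * np.pi)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule in 1-D: ``std * (3 n / 4) ** (-1/5)``.

    Matches the ``bw_method="silverman"`` convention of
    ``scipy.stats.gaussian_kde`` (sample standard deviation with one
    delta degree of freedom).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        raise DegenerateDataError("bandwidth needs at least 2 samples")
    sd = samples.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("bandwidth undefined for zero-variance samples")
    return float(sd * (0.75 * n) ** (-0.2))


@dataclass
class DensityEstimate:
    """Gaussian-kernel density estimate, evaluable at any finite value."""

    samples: np.ndarray
    bandwidth: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(s)):
            raise InvalidInputError("samples must be finite")
        if not (np.isfinite(self.bandwidth) and self.bandwidth > 0):
            raise InvalidInputError("bandwidth must be finite and > 0")
        self.samples = s

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.samples) / self.bandwidth
        dens = np.exp(-0.5 * z * z).sum(axis=-1) / (self.samples.size * self.bandwidth * _SQRT2PI)
        if dens.ndim == 0:
            return float(dens)
        return dens


def fit_kde(samples, bandwidth_rule: str = "silverman", bandwidth: float | None = None):
    """Fit a Gaussian KDE to work samples.

    ``bandwidth_rule`` is ``"silverman"`` (default) or ``"fixed"``; the
    latter requires an explicit ``bandwidth``.
    """
    samples = np.asarray(samples, dtype=float)
    if np.unique(samples).size < 2 and bandwidth_rule != "fixed":
        raise DegenerateDataError("KDE needs at least 2 distinct samples")
    if bandwidth_rule == "silverman":
        h = silverman_bandwidth(samples)
    elif bandwidth_rule == "fixed":
        if bandwidth is None:
            raise InvalidInputError("fixed bandwidth rule requires a bandwidth")
        h = float(bandwidth)
    else:
        raise InvalidInputError(f"unknown bandwidth rule {bandwidth_rule!r}")
    return DensityEstimate(samples=samples, bandwidth=h)


def _kde_rows(rows: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Row-wise Gaussian KDE evaluation: ``rows`` (B, n) -> densities (B, G).

    Bandwidths follow Silverman's rule per row; degenerate rows fall back
    to a tiny positive bandwidth (their density collapses onto the atoms).
    Evaluation is chunked to bound memory at large B * n * G.
    """
    rows = np.asarray(rows, dtype=float)
    B, n = rows.shape
    g = np.asarray(grid, dtype=float)
    h = rows.std(axis=1, ddof=1) * (0.75 * n) ** (-0.2)
    h = np.maximum(h, 1e-12)
    out = np.empty((B, g.size))
    chunk = max(1, int(2e7 / max(1, n * g.size)))
    for i in range(0, B, chunk):
        r = rows[i : i + chunk]
        hh = h[i : i + chunk, None, None]
        z = (g[None, None, :] - r[:, :, None]) / hh
        out[i : i + chunk] = np.exp(-0.5 * z * z).sum(axis=1) / (n * h[i : i + chunk, None] * _SQRT2PI)
    return out


@dataclass
class CrooksCurve:
    """Estimated Crooks log-density-ratio curve with bootstrap band.

    ``point_estimate`` is the plug-in curve from the full-sample KDEs;
    ``estimate`` is the mean bootstrap path; ``band_low``/``band_high``
    are pointwise percentile bounds; ``theory`` is the prediction
    ``w - delta_F``.  ``floored`` flags grid points where a full-sample
    density hit the positivity floor (log-ratio meaningless there);
    ``reliable`` marks the stricter trust region where both full-sample
    densities exceed ``min_density`` (the log-ratio variance grows like
    the inverse density, so points outside it are dominated by kernel
    tails).
    """

    grid: np.ndarray
    point_estimate: np.ndarray
    estimate: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    theory: np.ndarray
    floored: np.ndarray
    reliable: np.ndarray
    dens_forward: np.ndarray | None
    dens_backward: np.ndarray | None
    beta: float
    delta_F: float
    level: float
    n_boot: int
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w": self.grid,
                "estimate": self.estimate,
                "point_estimate": self.point_estimate,
                "band_low": self.band_low,
                "band_high": self.band_high,
                "theory": self.theory,
                "floored": self.floored,
                "reliable": self.reliable,
            }
        )

    def linear_fit(self) -> tuple[float, float]:
        """Weighted least-squares line through ``(w, point_estimate)``.

        Restricted to the ``reliable`` region and weighted by
        ``1 / (1/rhoF(w) + 1/rhoB(-w))``, the inverse of the leading-order
        variance of the log-density ratio, so sparse tails do not dominate.
        Returns ``(slope, intercept)``; the theory predicts slope 1 and
        intercept ``-delta_F``.
        """
        sel = self.reliable
        if sel.sum() < 3:
            raise DegenerateDataError("too few reliable grid points for a line fit")
        pf = np.maximum(self.dens_forward[sel], DENSITY_FLOOR)
        pb = np.maximum(self.dens_backward[sel], DENSITY_FLOOR)
        wt = np.sqrt(1.0 / (1.0 / pf + 1.0 / pb))
        a = np.vstack([self.grid[sel] * wt, wt]).T
        slope, intercept = np.linalg.lstsq(a, self.point_estimate[sel] * wt, rcond=None)[0]
        return float(slope), float(intercept)


def _check_estimator_args(beta, n_boot, level):
    if not (np.isfinite(beta) and beta > 0):
        raise InvalidInputError("beta must be finite and > 0")
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")


def crooks_curve(
    work: WorkSamples,
    beta: float,
    delta_F: float = 0.0,
    n_boot: int = 1000,
    level: float = 0.99,
    seed=None,
    grid_size: int = 101,
    bandwidth_rule: str = "silverman",
    bandwidth: float | None = None,
    min_density: float = 0.01,
) -> CrooksCurve:
    """Estimate ``(1/beta) log(rhoF(w) / rhoB(-w))`` with a bootstrap band.

    The evaluation grid is the union of the observed forward values and a
    uniform grid over their range.  Forward and backward sample sets are
    resampled independently with replacement, both KDEs are refit for each
    of the ``n_boot`` replicates, and the pointwise percentile band at the
    requested ``level`` is attached together with the theory line
    ``w - delta_F``.
    """
    _check_estimator_args(beta, n_boot, level)
    fwd = np.asarray(work.forward, dtype=float)
    bwd = np.asarray(work.backward, dtype=float)
    if np.unique(fwd).size < 2 or np.unique(bwd).size < 2:
        raise DegenerateDataError("forward and backward samples must be non-degenerate")
    grid = np.unique(
        np.concatenate([np.sort(fwd), np.linspace(fwd.min(), fwd.max(), grid_size)])
    )

    kf = fit_kde(fwd, bandwidth_rule, bandwidth)
    kb = fit_kde(bwd, bandwidth_rule, bandwidth)
    df_raw = kf(grid)
    db_raw = kb(-grid)
    floored = (df_raw <= DENSITY_FLOOR) | (db_raw <= DENSITY_FLOOR)
    reliable = (df_raw >= min_density) & (db_raw >= min_density)
    point = (
        np.log(np.maximum(df_raw, DENSITY_FLOOR)) - np.log(np.maximum(db_raw, DENSITY_FLOOR))
    ) / beta

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bf = fwd[rng.integers(0, fwd.size, size=(n_boot, fwd.size))]
    bb = bwd[rng.integers(0, bwd.size, size=(n_boot, bwd.size))]
    dens_f = np.maximum(_kde_rows(bf, grid), DENSITY_FLOOR)
    dens_b = np.maximum(_kde_rows(bb, -grid), DENSITY_FLOOR)
    paths = (np.log(dens_f) - np.log(dens_b)) / beta
    lo_q = 100.0 * (1.0 - level) / 2.0
    band_low, band_high = np.percentile(paths, [lo_q, 100.0 - lo_q], axis=0)

    return CrooksCurve(
        grid=grid,
        point_estimate=point,
        estimate=paths.mean(axis=0),
        band_low=band_low,
        band_high=band_high,
        theory=grid - delta_F,
        floored=floored,
        reliable=reliable,
        dens_forward=df_raw,
        dens_backward=db_raw,
        beta=float(beta),
        delta_F=float(delta_F),
        level=float(level),
        n_boot=int(n_boot),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


@dataclass
class JarzynskiResult:
    """Exponentiated-work average with a percentile bootstrap interval."""

    point_estimate: float
    ci_low: float
    ci_high: float
    level: float
    consistent: bool
    n_samples: int
    n_boot: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "point_estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "consistent": bool(self.consistent),
            "n_samples": self.n_samples,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def jarzynski(
    work: WorkSamples,
    beta: float,
    delta_F: float = 0.0,
    n_boot: int = 1000,
    level: float = 0.99,
    seed=None,
) -> JarzynskiResult:
    """Test ``< exp(-beta w) > = exp(-beta dF)`` on the forward samples.

    The point estimate is the sample mean of ``exp(-beta w)``; the CI is
    the percentile bootstrap of that mean; ``consistent`` records whether
    ``exp(-beta delta_F)`` falls inside the interval.
    """
    _check_estimator_args(beta, n_boot, level)
    fwd = np.asarray(work.forward, dtype=float)
    if fwd.size < 1:
        raise DegenerateDataError("need at least one forward sample")
    vals = np.exp(-beta * fwd)
    point = float(vals.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot_means = vals[rng.integers(0, vals.size, size=(n_boot, vals.size))].mean(axis=1)
    lo_q = 100.0 * (1.0 - level) / 2.0
    ci_low, ci_high = np.percentile(boot_means, [lo_q, 100.0 - lo_q])
    target = float(np.exp(-beta * delta_F))
    return JarzynskiResult(
        point_estimate=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=float(level),
        consistent=bool(ci_low <= target <= ci_high),
        n_samples=int(fwd.size),
        n_boot=int(n_boot),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
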