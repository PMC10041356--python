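"""Posterior-predictive bands and coverage summaries.

Predictive draws re-simulate with fresh noise at parameters resampled from
the final SMC population, so the bands reflect the full posterior
predictive distribution rather than the fitted residuals of stored
particle simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .smc import ABCProblem, ParticleSystem, SimulationError

__all__ = ["PredictiveBands", "posterior_predictive", "band_coverage"]

_MAX_RETRIES = 100


@dataclass(frozen=True)
class PredictiveBands:
    """Pointwise predictive quantiles of tumour volume over time."""

    days: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    n_draws: int
    level: float = 0.95

    def __post_init__(self) -> None:
        n = len(self.days)
        for name in ("lower", "median", "upper"):
            if len(getattr(self, name)) != n:
                raise ValueError("band arrays must match the day grid")
        if np.any(self.lower > self.median) or np.any(self.median > self.upper):
            raise ValueError("bands must satisfy lower <= median <= upper")


def posterior_predictive(
    system: ParticleSystem,
    problem: ABCProblem,
    days: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> PredictiveBands:
    """Draw ``n_draws`` parameters from the particle system (uniform with
    replacement), re-simulate each with fresh noise, and return pointwise
    lower/median/upper quantiles at the requested band level."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    days = np.asarray(days, dtype=float)
    draws = []
    while len(draws) < n_draws:
        idx = int(rng.integers(0, system.n))
        theta = system.particles[idx].theta
        for attempt in range(_MAX_RETRIES):
            try:
                draws.append(problem.simulate(theta, rng))
                break
            except SimulationError:
                idx = int(rng.integers(0, system.n))
                theta = system.particles[idx].theta
        else:
            raise SimulationError("predictive draw failed after retries")
    mat = np.asarray(draws, dtype=float)
    if mat.shape[1] != len(days):
        raise ValueError("simulator output does not match the day grid")
    tail = (1.0 - level) / 2.0
    lower, median, upper = np.quantile(mat, [tail, 0.5, 1.0 - tail], axis=0)
    return PredictiveBands(days, lower, median, upper, n_draws, level)


def band_coverage(bands: PredictiveBands, days: np.ndarray, volumes: np.ndarray) -> float:
    """Fraction of observed points falling inside [lower, upper]."""
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if len(days) != len(bands.days) or not np.allclose(days, bands.days):
        raise ValueError("observation days do not match the band day grid")
    inside = (volumes >= bands.lower) & (volumes <= bands.upper)
    return float(np.mean(inside))
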