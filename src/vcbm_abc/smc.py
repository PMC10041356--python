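"""Adaptive replenishment SMC-ABC.

The engine targets the ABC posterior

    p_eps(theta | y)  ∝  pi(theta) * Pr( ||x - y|| <= eps | theta ),

for any stochastic simulator, by evolving N particles through a decreasing
tolerance schedule:

(i)   draw N particles from the prior, simulate each, set eps to the
      largest distance;
(ii)  drop the next eps to the alpha-quantile of the current distances and
      retain the N*alpha particles within it;
(iii) resample the retained set back up to N particles;
(iv)  diversify each resampled particle with a Metropolis–Hastings move
      whose stationary distribution is the ABC posterior at the current
      eps (Gaussian random walk on an unconstrained scale; a proposal is
      accepted when the prior ratio passes AND one fresh simulation lands
      within eps); the number of MH repeats adapts to the observed
      acceptance rate;
(v)   repeat until eps reaches its target, the MH acceptance rate
      collapses, or the simulation budget is spent.

Everything problem-specific (prior, transform, simulator, distance) is
bundled in :class:`ABCProblem`; :func:`vcbm_problem` builds the bundle for
the tumour-growth model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .priors import (
    PriorSpec,
    inverse_transform,
    log_jacobian,
    log_prior_density,
    sample_prior,
    transform,
)
from .simulator import (
    SimConfig,
    TumourTimeSeries,
    VCBMParams,
    pad_series,
    simulate,
)

__all__ = [
    "ABCProblem",
    "SMCConfig",
    "Particle",
    "ParticleSystem",
    "IterationRecord",
    "InitializationError",
    "DegeneracyError",
    "SimulationError",
    "series_distance",
    "log_volume_distance",
    "raw_volume_distance",
    "vcbm_problem",
    "initialize",
    "next_tolerance",
    "retain_and_resample",
    "tune_proposal",
    "tune_n_mcmc_iter",
    "mcmc_move",
    "run_smc_abc",
]


class InitializationError(RuntimeError):
    """Could not initialise the particle system within the budget."""


class DegeneracyError(RuntimeError):
    """No particles satisfy the new tolerance."""


class SimulationError(RuntimeError):
    """A simulator call failed; the draw is retried against the budget."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def log_volume_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between log(volume + 1) vectors.

    The log transform stops late, large volumes from dominating the norm.
    """
    return float(np.linalg.norm(np.log1p(x) - np.log1p(y)))


def raw_volume_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Euclidean distance between volume vectors."""
    return float(np.linalg.norm(np.asarray(x, float) - np.asarray(y, float)))


def series_distance(
    x: TumourTimeSeries, y: TumourTimeSeries, metric: str = "log"
) -> float:
    """Distance between two tumour-volume series on a shared day grid."""
    if len(x.days) != len(y.days) or not np.allclose(x.days, y.days):
        raise ValueError("series are on different day grids")
    f = log_volume_distance if metric == "log" else raw_volume_distance
    return f(x.volumes, y.volumes)


# ---------------------------------------------------------------------------
# problem bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ABCProblem:
    """Everything the engine needs to know about one inference problem.

    Parameters are plain length-``dim`` vectors; ``simulate`` returns the
    data vector compared by ``distance``.
    """

    dim: int
    sample_prior: Callable[[int, np.random.Generator], np.ndarray]  # (n, dim)
    log_prior: Callable[[np.ndarray], float]
    to_unconstrained: Callable[[np.ndarray], np.ndarray]
    from_unconstrained: Callable[[np.ndarray], np.ndarray]
    log_jacobian: Callable[[np.ndarray], float]
    simulate: Callable[[np.ndarray, np.random.Generator], np.ndarray]
    distance: Callable[[np.ndarray, np.ndarray], float]


def vcbm_problem(
    priors: PriorSpec,
    sim_config: SimConfig,
    days: np.ndarray,
    metric: str = "log",
) -> ABCProblem:
    """ABC problem bundle for the VCBM: simulate a volume series on the
    observation day grid (carry-forward padded if truncated) and compare
    with the configured metric."""
    days = np.asarray(days, dtype=float)
    dist = log_volume_distance if metric == "log" else raw_volume_distance

    def _sample(n: int, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.as_array() for p in sample_prior(priors, n, rng)])

    def _simulate(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        series = simulate(VCBMParams.from_array(theta), sim_config, rng)
        return pad_series(series, days).volumes

    return ABCProblem(
        dim=4,
        sample_prior=_sample,
        log_prior=lambda t: log_prior_density(VCBMParams.from_array(t), priors),
        to_unconstrained=lambda t: transform(VCBMParams.from_array(t), priors),
        from_unconstrained=lambda z: inverse_transform(z, priors).as_array(),
        log_jacobian=lambda z: log_jacobian(z, priors),
        simulate=_simulate,
        distance=dist,
    )


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SMCConfig:
    """Engine settings.

    ``c_tune`` is the target probability that a resampled particle is left
    unmoved by the MCMC step; the number of MH repeats per iteration is
    ceil(log c_tune / log(1 - acceptance_rate)), capped at
    ``max_mcmc_iter``.
    """

    n_particles: int = 100
    alpha: float = 0.5
    target_epsilon: float | None = None
    min_acceptance: float = 0.01
    max_simulations: int = 20_000
    c_tune: float = 0.01
    max_mcmc_iter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")
        if self.n_particles < 10:
            raise ValueError("need at least 10 particles")
        if not (0.0 < self.min_acceptance < 1.0):
            raise ValueError("min_acceptance must be in (0,1)")
        if not (0.0 < self.c_tune < 1.0):
            raise ValueError("c_tune must be in (0,1)")
        if self.max_simulations <= 0 or self.max_mcmc_iter <= 0:
            raise ValueError("budgets must be positive")


@dataclass
class Particle:
    """One parameter vector with its latest accepted simulation and the
    corresponding distance to the observed data."""

    theta: np.ndarray
    x: np.ndarray
    distance: float


@dataclass
class ParticleSystem:
    """The evolving SMC population."""

    particles: list[Particle]
    epsilon: float
    iteration: int = 0
    n_simulations: int = 0
    acceptance_rate: float = 1.0

    @property
    def n(self) -> int:
        return len(self.particles)

    @property
    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.particles])

    @property
    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.particles])


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    epsilon: float
    acceptance_rate: float
    n_simulations: int


def _sim_rng(seed: int, iteration: int, particle: int) -> np.random.Generator:
    """Independent, reproducible stream for one particle's simulations in
    one iteration, keyed on (global seed, iteration, particle index)."""
    return np.random.default_rng(np.random.SeedSequence([seed, iteration, particle]))


# ---------------------------------------------------------------------------
# algorithm pieces
# ---------------------------------------------------------------------------

def initialize(
    y_obs: np.ndarray,
    problem: ABCProblem,
    config: SMCConfig,
) -> ParticleSystem:
    """Step (i): N prior draws, one simulation each; eps starts at the
    largest distance."""
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    particles: list[Particle] = []
    n_sims = 0
    attempts = 0
    while len(particles) < config.n_particles:
        if n_sims >= config.max_simulations:
            raise InitializationError(
                f"budget {config.max_simulations} exhausted after "
                f"{len(particles)} particles"
            )
        theta = problem.sample_prior(1, master)[0]
        rng = _sim_rng(config.seed, 0, attempts)
        attempts += 1
        n_sims += 1
        try:
            x = problem.simulate(theta, rng)
        except SimulationError:
            continue
        particles.append(Particle(theta, x, problem.distance(x, y_obs)))
    eps = float(max(p.distance for p in particles))
    return ParticleSystem(particles, epsilon=eps, iteration=0, n_simulations=n_sims)


def next_tolerance(distances: np.ndarray, alpha: float) -> float:
    """Step (ii): the alpha-quantile of the distances, lower (inverse-ecdf)
    convention — the ceil(alpha*N)-th smallest — so that exactly
    ceil(alpha*N) particles satisfy distance <= eps."""
    distances = np.sort(np.asarray(distances, dtype=float))
    if len(distances) == 0:
        raise ValueError("empty distance list")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    k = math.ceil(alpha * len(distances))
    return float(distances[k - 1])


def retain_and_resample(
    system: ParticleSystem,
    epsilon_new: float,
    rng: np.random.Generator,
    alpha: float,
) -> tuple[ParticleSystem, np.ndarray]:
    """Steps (ii)-(iii): keep the N*alpha closest particles, then resample
    uniformly with replacement back up to N.  Returns the new system and
    the indices (into the new particle list) of the resampled copies."""
    n = system.n
    n_keep = math.ceil(alpha * n)
    order = np.argsort(system.distances, kind="stable")
    keep_idx = order[:n_keep]
    retained = [system.particles[i] for i in keep_idx]
    if not all(p.distance <= epsilon_new for p in retained):
        raise DegeneracyError("retained particle exceeds the new tolerance")
    copies = rng.integers(0, n_keep, size=n - n_keep)
    new_particles = retained + [
        Particle(
            retained[c].theta.copy(), retained[c].x.copy(), retained[c].distance
        )
        for c in copies
    ]
    moved_idx = np.arange(n_keep, n)
    out = ParticleSystem(
        new_particles,
        epsilon=float(epsilon_new),
        iteration=system.iteration,
        n_simulations=system.n_simulations,
        acceptance_rate=system.acceptance_rate,
    )
    return out, moved_idx


def tune_proposal(thetas_z: np.ndarray) -> np.ndarray:
    """Random-walk proposal covariance: empirical covariance of the
    particles on the unconstrained scale, scaled by 2.38^2/d, with a small
    diagonal jitter; falls back to the diagonal of marginal variances if
    the full matrix is singular."""
    z = np.asarray(thetas_z, dtype=float)
    d = z.shape[1]
    scale = 2.38**2 / d
    jitter = 1e-8 * np.eye(d)
    cov = scale * np.atleast_2d(np.cov(z.T)) + jitter
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = scale * np.diag(z.var(axis=0, ddof=1)) + jitter
    return cov


def tune_n_mcmc_iter(acceptance_rate: float, c_tune: float, max_iter: int) -> int:
    """Number of MH repeats so that a particle stays unmoved with
    probability at most ``c_tune``: ceil(log c / log(1 - acc)), capped."""
    if not (0.0 <= acceptance_rate <= 1.0):
        raise ValueError("acceptance rate must be in [0,1]")
    if acceptance_rate >= 1.0:
        return 1
    if acceptance_rate <= 0.0:
        return max_iter
    n = math.ceil(math.log(c_tune) / math.log(1.0 - acceptance_rate))
    return int(min(max(n, 1), max_iter))


def mcmc_move(
    particle: Particle,
    y_obs: np.ndarray,
    epsilon: float,
    problem: ABCProblem,
    proposal_cov: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    budget_left: int | None = None,
) -> tuple[Particle, int, int, int]:
    """Step (iv): ``n_iter`` MH steps targeting the ABC posterior at
    ``epsilon``.

    A Gaussian random-walk proposal on the unconstrained scale is accepted
    iff the prior (x Jacobian) MH ratio passes a uniform draw AND one fresh
    simulation at the proposal lands within ``epsilon``.  The simulation is
    skipped when the prior ratio already fails, saving budget without
    changing the stationary distribution.

    Returns (particle, accepted, proposals, simulations_used).
    """
    chol = np.linalg.cholesky(proposal_cov)
    z = problem.to_unconstrained(particle.theta)
    log_post = problem.log_prior(particle.theta) + problem.log_jacobian(z)
    accepted = 0
    n_sims = 0
    proposals = 0
    for _ in range(n_iter):
        if budget_left is not None and n_sims >= budget_left:
            break
        proposals += 1
        z_prop = z + chol @ rng.standard_normal(len(z))
        if not np.all(np.isfinite(z_prop)):
            continue
        theta_prop = problem.from_unconstrained(z_prop)
        log_post_prop = problem.log_prior(theta_prop) + problem.log_jacobian(z_prop)
        if not np.isfinite(log_post_prop):
            continue
        if np.log(rng.uniform()) >= log_post_prop - log_post:
            continue
        n_sims += 1
        try:
            x_prop = problem.simulate(theta_prop, rng)
        except SimulationError:
            continue
        dist = problem.distance(x_prop, y_obs)
        if dist <= epsilon:
            particle = Particle(theta_prop, x_prop, dist)
            z, log_post = z_prop, log_post_prop
            accepted += 1
    return particle, accepted, proposals, n_sims


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_smc_abc(
    y_obs: np.ndarray,
    problem: ABCProblem,
    config: SMCConfig,
    progress: Callable[[IterationRecord], None] | None = None,
) -> tuple[ParticleSystem, list[IterationRecord]]:
    """Run the full adaptive SMC-ABC loop; returns the final particle
    system and the per-iteration trace."""
    y_obs = np.asarray(y_obs, dtype=float)
    system = initialize(y_obs, problem, config)
    trace: list[IterationRecord] = [
        IterationRecord(0, system.epsilon, 1.0, system.n_simulations)
    ]
    if progress:
        progress(trace[-1])
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    acc_rate = 0.5  # optimistic starting guess, refined after one iteration
    iteration = 0
    while True:
        iteration += 1
        eps_new = next_tolerance(system.distances, config.alpha)
        system, moved_idx = retain_and_resample(system, eps_new, master, config.alpha)
        system.iteration = iteration
        cov = tune_proposal(
            np.array([problem.to_unconstrained(p.theta) for p in system.particles])
        )
        n_iter = tune_n_mcmc_iter(acc_rate, config.c_tune, config.max_mcmc_iter)
        tot_acc = tot_prop = 0
        for j in moved_idx:
            budget_left = config.max_simulations - system.n_simulations
            if budget_left <= 0:
                break
            rng = _sim_rng(config.seed, iteration, int(j))
            particle, acc, prop, sims = mcmc_move(
                system.particles[j], y_obs, system.epsilon, problem,
                cov, n_iter, rng, budget_left,
            )
            system.particles[j] = particle
            tot_acc += acc
            tot_prop += prop
            system.n_simulations += sims
        acc_rate = tot_acc / tot_prop if tot_prop else 0.0
        system.acceptance_rate = acc_rate
        trace.append(
            IterationRecord(iteration, system.epsilon, acc_rate, system.n_simulations)
        )
        if progress:
            progress(trace[-1])
        if config.target_epsilon is not None and system.epsilon <= config.target_epsilon:
            break
        if acc_rate < config.min_acceptance:
            break
        if system.n_simulations >= config.max_simulations:
            break
    return system, trace
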