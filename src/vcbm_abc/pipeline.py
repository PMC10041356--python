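"""Three-stage pipeline: simulate -> calibrate -> predict.

Two named profiles are provided.  The *reference* profile mirrors the
in-vivo caliper study design (32 days measured every 2 days, hourly
timesteps, a wide healthy annulus).  The *desk* profile is the scaled-down
configuration used for fast calibration studies: a 14-day horizon, 2-hour
timesteps (per-step spring mobility unchanged), a 3-cell-diameter tumour
in a 4-diameter annulus, and a few hundred simulations per SMC run.  The
desk profile is what the bundled recovery study and the acceptance runs
use; its sizes are a deliberate compromise so that a full 10-replicate
calibration finishes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .io import config_hash, read_series, write_series
from .predictive import PredictiveBands, band_coverage, posterior_predictive
from .priors import (
    PARAM_NAMES,
    PriorSpec,
    ReferenceDataset,
    REFERENCE_PARAMS,
    default_priors,
    generate_reference,
)
from .simulator import SimConfig, TumourTimeSeries, VCBMParams
from .smc import (
    ABCProblem,
    IterationRecord,
    ParticleSystem,
    SMCConfig,
    run_smc_abc,
    vcbm_problem,
)

__all__ = [
    "desk_sim_config",
    "desk_smc_config",
    "reference_sim_config",
    "PipelineResult",
    "calibrate",
    "predict",
    "run_pipeline",
    "particles_frame",
    "trace_frame",
    "credible_interval",
]

log = logging.getLogger("vcbm_abc")


def reference_sim_config(**overrides) -> SimConfig:
    """Simulator settings mirroring the caliper study design: 32 days
    measured every 2 days, hourly steps, radius-3 tumour, width-15 healthy
    annulus."""
    return SimConfig(**overrides)


def desk_sim_config(**overrides) -> SimConfig:
    """Scaled-down simulator settings for desk-scale calibration.

    3-hour steps with the damping rescaled so the per-step spring mobility
    stays at 0.1; 14 days measured every 2 days; width-4 annulus; runaway
    growth capped at 800 cells (an order of magnitude above the volumes the
    14-day reference regime reaches).
    """
    base = dict(
        dt=3.0,
        damping=30.0,
        n_days=14.0,
        measure_every=2.0,
        init_cancer_radius=3.0,
        domain_pad=4.0,
        max_cells=800,
    )
    base.update(overrides)
    return SimConfig(**base)


def desk_smc_config(seed: int = 0, **overrides) -> SMCConfig:
    """SMC settings for desk-scale runs: 100 particles, alpha = 0.5, a
    400-simulation budget (initialisation plus roughly three tolerance
    drops)."""
    base = dict(
        n_particles=100,
        alpha=0.5,
        max_simulations=400,
        min_acceptance=0.01,
        max_mcmc_iter=10,
        seed=seed,
    )
    base.update(overrides)
    return SMCConfig(**base)


@dataclass
class PipelineResult:
    reference: ReferenceDataset | None
    observed: TumourTimeSeries
    system: ParticleSystem
    trace: list[IterationRecord]
    bands: PredictiveBands
    coverage: float
    problem: ABCProblem


def calibrate(
    observed: TumourTimeSeries,
    priors: PriorSpec,
    sim_config: SimConfig,
    smc_config: SMCConfig,
    metric: str = "log",
) -> tuple[ParticleSystem, list[IterationRecord], ABCProblem]:
    """Run SMC-ABC against an observed volume series."""
    problem = vcbm_problem(priors, sim_config, observed.days, metric=metric)

    def _log(rec: IterationRecord) -> None:
        log.info(
            "iteration %d: epsilon=%.4g acceptance=%.3f simulations=%d",
            rec.iteration, rec.epsilon, rec.acceptance_rate, rec.n_simulations,
        )

    system, trace = run_smc_abc(observed.volumes, problem, smc_config, progress=_log)
    return system, trace, problem


def predict(
    system: ParticleSystem,
    problem: ABCProblem,
    observed: TumourTimeSeries,
    n_draws: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[PredictiveBands, float]:
    """Posterior-predictive bands plus their coverage of the observation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    bands = posterior_predictive(
        system, problem, observed.days, n_draws, rng, level=level
    )
    return bands, band_coverage(bands, observed.days, observed.volumes)


def particles_frame(system: ParticleSystem) -> pd.DataFrame:
    df = pd.DataFrame(system.thetas, columns=list(PARAM_NAMES))
    df["distance"] = system.distances
    return df


def trace_frame(trace: list[IterationRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in trace])


def credible_interval(
    samples: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior samples."""
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(samples, float), [tail, 1.0 - tail])
    return float(lo), float(hi)


def run_pipeline(
    out_dir: str | Path,
    data_path: str | Path | None = None,
    sim_config: SimConfig | None = None,
    smc_config: SMCConfig | None = None,
    priors: PriorSpec | None = None,
    generating_params: VCBMParams = REFERENCE_PARAMS,
    n_predictive_draws: int = 200,
    band_level: float = 0.95,
    metric: str = "log",
    seed: int = 0,
) -> PipelineResult:
    """End-to-end run: synthesise (or load) the data, calibrate, predict.

    Writes ``reference.csv`` (when data are synthesised), ``particles.csv``,
    ``trace.csv``, ``bands.csv`` and ``metadata.json`` under ``out_dir``;
    identical (config, seed) pairs produce identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_config = sim_config if sim_config is not None else desk_sim_config()
    smc_config = smc_config if smc_config is not None else desk_smc_config(seed=seed)
    priors = priors if priors is not None else default_priors()

    reference = None
    if data_path is None:
        log.info("stage simulate: generating synthetic reference dataset")
        reference = generate_reference(generating_params, sim_config, seed=seed)
        observed = reference.series
        write_series(observed, out / "reference.csv")
    else:
        log.info("stage simulate: skipped, loading %s", data_path)
        observed = read_series(data_path)

    log.info("stage calibrate: N=%d budget=%d", smc_config.n_particles,
             smc_config.max_simulations)
    system, trace, problem = calibrate(observed, priors, sim_config, smc_config,
                                       metric=metric)
    particles_frame(system).to_csv(out / "particles.csv", index=False)
    trace_frame(trace).to_csv(out / "trace.csv", index=False)

    log.info("stage predict: %d draws at level %.2f", n_predictive_draws, band_level)
    bands, coverage = predict(system, problem, observed,
                              n_draws=n_predictive_draws, level=band_level,
                              seed=seed)
    pd.DataFrame({
        "day": bands.days, "lower": bands.lower,
        "median": bands.median, "upper": bands.upper,
    }).to_csv(out / "bands.csv", index=False)

    echo = {
        "seed": seed,
        "sim_config": dataclasses.asdict(sim_config),
        "smc_config": dataclasses.asdict(smc_config),
        "priors": {k: dataclasses.asdict(priors[k]) for k in PARAM_NAMES},
        "metric": metric,
        "band_level": band_level,
        "n_predictive_draws": n_predictive_draws,
    }
    meta = {
        "version": _version,
        "config": echo,
        "config_hash": config_hash(echo),
        "final_epsilon": system.epsilon,
        "n_simulations": system.n_simulations,
        "band_coverage": coverage,
        "truncated_reference": bool(observed.truncated),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return PipelineResult(reference, observed, system, trace, bands, coverage, problem)
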