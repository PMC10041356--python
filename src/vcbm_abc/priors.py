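"""Priors, transforms, and the synthetic reference dataset.

The four VCBM parameters get independent priors:

* ``p0   ~ Beta(1, 1)`` (uniform on [0, 1])
* ``ppsc ~ Beta(1, 10^4)`` (invasion events are rare)
* ``dmax ~ LogNormal(log 30, 1)`` (median 30 cell diameters)
* ``gage ~ LogNormal(log 160, 1)`` (median 160 hours)

MCMC moves operate on an unconstrained scale: logit for the Beta-supported
parameters, log for the LogNormal-supported ones.  The synthetic reference
dataset — standing in for in-vivo caliper measurements — is a single VCBM
draw at the generating value theta = (0.2, 1e-5, 31, 114).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .simulator import SimConfig, TumourTimeSeries, VCBMParams, simulate

__all__ = [
    "MarginalPrior",
    "PriorSpec",
    "ReferenceDataset",
    "REFERENCE_PARAMS",
    "default_priors",
    "sample_prior",
    "log_prior_density",
    "transform",
    "inverse_transform",
    "log_jacobian",
    "generate_reference",
]

PARAM_NAMES = ("p0", "ppsc", "dmax", "gage")

#: generating parameter value for the synthetic reference dataset
REFERENCE_PARAMS = VCBMParams(p0=0.2, ppsc=1e-5, dmax=31.0, gage=114.0)


@dataclass(frozen=True)
class MarginalPrior:
    """One parameter's prior: family, hyperparameters, and the transform
    that maps its support to the real line."""

    family: str          # "beta" or "lognormal"
    a: float             # beta: shape1;  lognormal: log-scale mean mu
    b: float             # beta: shape2;  lognormal: log-scale sd sigma

    def __post_init__(self) -> None:
        if self.family not in ("beta", "lognormal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "beta" and (self.a <= 0 or self.b <= 0):
            raise ValueError("beta shapes must be > 0")
        if self.family == "lognormal" and self.b <= 0:
            raise ValueError("lognormal sigma must be > 0")

    @property
    def dist(self):
        if self.family == "beta":
            return stats.beta(self.a, self.b)
        return stats.lognorm(s=self.b, scale=np.exp(self.a))

    @property
    def transform_name(self) -> str:
        return "logit" if self.family == "beta" else "log"


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors for the four VCBM parameters, keyed p0, ppsc,
    dmax, gage."""

    marginals: dict[str, MarginalPrior]

    def __post_init__(self) -> None:
        if tuple(self.marginals) != PARAM_NAMES:
            raise ValueError(f"priors must be keyed exactly {PARAM_NAMES}")

    def __getitem__(self, name: str) -> MarginalPrior:
        return self.marginals[name]


def default_priors() -> PriorSpec:
    """The priors used for the tumour-growth calibration."""
    return PriorSpec(
        {
            "p0": MarginalPrior("beta", 1.0, 1.0),
            "ppsc": MarginalPrior("beta", 1.0, 1.0e4),
            "dmax": MarginalPrior("lognormal", np.log(30.0), 1.0),
            "gage": MarginalPrior("lognormal", np.log(160.0), 1.0),
        }
    )


def sample_prior(
    priors: PriorSpec, n: int, rng: np.random.Generator
) -> list[VCBMParams]:
    """Draw ``n`` independent parameter vectors from the prior."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = []
    for name in PARAM_NAMES:
        m = priors[name]
        if m.family == "beta":
            cols.append(rng.beta(m.a, m.b, size=n))
        else:
            cols.append(np.exp(rng.normal(m.a, m.b, size=n)))
    draws = np.column_stack(cols)
    return [VCBMParams.from_array(row) for row in draws]


def log_prior_density(params: VCBMParams, priors: PriorSpec) -> float:
    """Joint log prior density (nats); -inf outside the support."""
    total = 0.0
    for name, value in zip(PARAM_NAMES, params.as_array()):
        lp = priors[name].dist.logpdf(value)
        if not np.isfinite(lp):
            return -np.inf
        total += float(lp)
    return total


def transform(params: VCBMParams, priors: PriorSpec) -> np.ndarray:
    """Map a parameter vector to the unconstrained 4-vector
    (logit for Beta-supported entries, log for LogNormal-supported)."""
    z = np.empty(4)
    for k, (name, value) in enumerate(zip(PARAM_NAMES, params.as_array())):
        z[k] = logit(value) if priors[name].transform_name == "logit" else np.log(value)
    return z


def inverse_transform(z: np.ndarray, priors: PriorSpec) -> VCBMParams:
    """Map an unconstrained 4-vector back to the parameter space."""
    theta = np.empty(4)
    for k, name in enumerate(PARAM_NAMES):
        theta[k] = expit(z[k]) if priors[name].transform_name == "logit" else np.exp(z[k])
    return VCBMParams.from_array(theta)


def log_jacobian(z: np.ndarray, priors: PriorSpec) -> float:
    """Log |d theta / d z| of the inverse transform at ``z``.

    logit^-1 contributes log sigma(z) + log sigma(-z); exp contributes z.
    """
    total = 0.0
    for k, name in enumerate(PARAM_NAMES):
        if priors[name].transform_name == "logit":
            # log derivative of expit: -log(1+e^-z) - log(1+e^z), stably
            total += -np.logaddexp(0.0, -z[k]) - np.logaddexp(0.0, z[k])
        else:
            total += z[k]
    return float(total)


@dataclass(frozen=True)
class ReferenceDataset:
    """A tumour-volume series with full generative provenance."""

    series: TumourTimeSeries
    generating_params: VCBMParams | None
    seed: int
    config: SimConfig


def generate_reference(
    params: VCBMParams = REFERENCE_PARAMS,
    config: SimConfig | None = None,
    seed: int = 0,
) -> ReferenceDataset:
    """One VCBM draw at ``params`` (default: the synthetic generating value
    theta = (0.2, 1e-5, 31, 114)), with provenance recorded."""
    if config is None:
        config = SimConfig()
    series = simulate(params, config, np.random.default_rng(seed))
    return ReferenceDataset(series, params, seed, config)
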