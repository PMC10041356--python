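# vcbm-abc

Likelihood-free Bayesian calibration of a two-dimensional Voronoi
cell-based model (VCBM) of tumour growth, using an adaptive replenishment
sequential Monte Carlo ABC (SMC-ABC) sampler, with posterior-predictive
checking. The package is aimed at modellers calibrating stochastic
agent-based tumour models against caliper-style tumour-volume time series
(e.g. murine xenograft measurements), where the model can only be
simulated, never evaluated as a likelihood.

## The model

Cancer and healthy cells are point agents in the plane; each cell's
boundary is the Voronoi region of its centre and its neighbours are given
by the dual Delaunay triangulation. Per timestep:

* **Invasion** — each cancer cell on the tumour–tissue interface converts
  a uniformly chosen healthy Delaunay neighbour with probability
  `p_psc`.
* **Proliferation** — a cancer cell older than `g_age` attempts division
  with probability `P = p_0 (1 − d/d_max)`, where `d` is the distance from
  its centre to the nearest healthy cell centre (the tumour boundary) and
  `d_max` the largest distance at which division is still possible. A
  daughter is placed next to the mother and both ages reset.
* **Mechanics** — cells relax along Delaunay edges under overdamped
  Hookean spring forces, capturing pressure-driven off-lattice movement;
  the triangulation is then rebuilt.

Tumour volume is read off the cancer-cell cloud with the standard caliper
formula `V = L·W²/2` (length and width along the principal axes, each
padded by one cell diameter). The calibration parameter is
`θ = (p_0, p_psc, d_max, g_age)` with independent priors
`p_0 ~ Beta(1,1)`, `p_psc ~ Beta(1,10⁴)`, `d_max ~ LogNormal(log 30, 1)`,
`g_age ~ LogNormal(log 160, 1)`.

## The sampler

SMC-ABC targets the approximate posterior
`p_ε(θ|y) ∝ π(θ) ∫ p(x|θ) 1(‖x−y‖ ≤ ε) dx` with
`‖x−y‖` the Euclidean norm between `log(volume+1)` vectors on the shared
measurement days. N particles are drawn from the prior; the tolerance ε is
repeatedly dropped to the α-quantile of the particle distances, the
retained particles are resampled back up to N, and each resampled particle
is diversified by Metropolis–Hastings moves (Gaussian random walk on the
logit/log-transformed scale) whose stationary distribution is the ABC
posterior at the current ε. The number of MH repeats adapts to the
observed acceptance rate; the run stops at a target ε, at an acceptance
rate collapse, or when the simulation budget is spent.

## Worked example

Calibrate against a synthetic dataset generated from the model itself at
`θ = (0.2, 1e-5, 31, 114)` using the fast desk-scale profile:

```python
import numpy as np
from vcbm_abc import run_pipeline
from vcbm_abc.pipeline import credible_interval

res = run_pipeline("out", seed=1)   # simulate -> calibrate -> predict
for r in res.trace:
    print(f"iter {r.iteration}: eps={r.epsilon:.3f} "
          f"acc={r.acceptance_rate:.2f} sims={r.n_simulations}")
p0 = res.system.thetas[:, 0]; gage = res.system.thetas[:, 3]
print("p0   95% CI", np.round(credible_interval(p0), 3))
print("gage 95% CI", np.round(credible_interval(gage), 1))
print("predictive band coverage:", res.coverage)
```

prints

```
iter 0: eps=1.968 acc=1.00 sims=100
iter 1: eps=1.052 acc=0.22 sims=217
iter 2: eps=0.566 acc=0.22 sims=376
iter 3: eps=0.355 acc=0.15 sims=400
p0   95% CI [0.063 0.958]
gage 95% CI [101.4 165.6]
predictive band coverage: 1.0
```

The tolerance falls by a factor of five to six over three iterations of
the 400-simulation budget. The cell-cycle gate `g_age` is sharply identified
(its 95% credible interval brackets the generating value 114 h tightly),
while `p_0` remains diffuse — growth timing is dominated by the age gate,
so the per-attempt division probability is only weakly constrained by a
single volume series (see `docs/methods.md`). The 95% posterior-predictive
band encloses all synthetic observations.

The same stages are available from a shell via
`vcbm-abc simulate | calibrate | predict | run-all`; a flat YAML config
file overrides any simulator, prior, SMC or predictive setting. Artifacts
(`reference.csv`, `particles.csv`, `trace.csv`, `bands.csv`,
`metadata.json`) carry the seed and a config hash, and reruns with the
same seed are byte-identical.

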