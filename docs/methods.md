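# Methods

## Model

The simulator is an off-lattice agent-based model of avascular tumour
growth in two dimensions. Cell centres are points; neighbourhood structure
is the Delaunay triangulation of the centres (equivalently, cells are the
Voronoi regions of their centres). Two agent types exist: cancer cells and
healthy tissue cells. There is no cell death, no oxygen or vasculature
coupling, and no treatment effect; the cancer population is therefore
non-decreasing.

Each timestep of length `dt` applies three sub-steps in a fixed order —
invasion, proliferation, mechanics — with a single adjacency rebuild at
the end (inside the mechanics update). The ordering is a convention: the
sub-steps commute only approximately, and fixing one order keeps runs
reproducible and documentable.

**Proliferation.** A cancer cell becomes division-competent once its age
reaches `g_age` (hours, converted to timesteps by `ceil(g_age/dt)`). A
competent cell divides in a given step with probability
`P = p_0 (1 − d/d_max)`, clamped to zero for `d ≥ d_max`, where `d` is the
Euclidean distance from the cell centre to the nearest healthy cell
centre. On division a daughter is placed at `daughter_offset = 0.5` cell
diameters in a uniform random direction and both ages reset to zero
(spring relaxation then pushes the pair apart over subsequent steps). Cells
that do not divide age by one step. Under this convention the effective
cell cycle is `g_age + (waiting time of a geometric trial with success
probability P)`; because `dt/P ≪ g_age` over most of the prior, the cycle
is dominated by `g_age` — a fact with consequences for identifiability
(below).

**Invasion.** Each boundary cancer cell (one with at least one healthy
Delaunay neighbour) independently converts a uniformly chosen healthy
neighbour into a cancer cell with probability `p_psc` per step. Two
boundary cells may select the same target; the conversion then happens
once. The event model for `p_psc` is one reading of "invasion
probability"; the original cell-based model literature should be consulted
where fidelity to a specific published variant matters.

**Mechanics.** Overdamped Hookean dynamics: cell `i` moves by
`(dt·k/η) Σ_j (|x_j − x_i| − L₀) û_ij` over Delaunay neighbours `j`, with
spring constant `k`, damping `η` and rest length `L₀ = 1` cell diameter.
Positions update synchronously, so pairwise forces cancel and total
momentum is conserved each step. The per-step mobility `k·dt/η` is fixed
at 0.1 in every shipped profile, which keeps the explicit update far from
the oscillatory instability (the 1-D stability limit is mobility < 0.5 for
a chain; 0.1 leaves a wide margin with growing, irregular neighbourhoods).
If a position update ever produced a non-finite coordinate the step raises
rather than continuing silently. When the point set is degenerate (fewer
than three cells, or collinear — possible only in synthetic test
geometries) the existing spring network is kept instead of re-triangulating.

**Measurement.** Tumour volume uses the standard two-caliper xenograft
approximation `V = L·W²/2`. `L` and `W` are the extents of the cancer-cell
cloud along its two principal axes (eigenvectors of the scatter matrix),
each padded by one cell diameter to account for finite cell size, with
`L ≥ W`. The construction is rotation-equivariant; a single cell measures
`1·1²/2 = 0.5`. Volumes are in cell-diameter³ units; they are compared
only with volumes produced the same way, so no absolute calibration to
mm³ is attempted.

**Initial condition and guards.** Cells start on a hexagonal lattice with
unit spacing and 5% positional jitter: cancer inside a disk of radius
`init_cancer_radius`, healthy in a surrounding annulus of width
`domain_pad`, all ages zero. Two terminal guards truncate a run at the
last completed measurement and flag it: exhaustion of healthy cells
(boundary distance undefined) and a `max_cells` cap. The cap exists
because prior draws with large `p_0` and small `g_age` grow exponentially
far beyond the observable regime; capped runs are padded by carrying the
last volume forward and are rejected by the distance, so the posterior is
unaffected while prior exploration stays bounded.

## Priors and transforms

`p_0 ~ Beta(1,1)`, `p_psc ~ Beta(1,10⁴)`, `d_max ~ LogNormal(log 30, 1)`,
`g_age ~ LogNormal(log 160, 1)`, independent. `g_age`'s prior is on the
hour scale (median 160 h ≈ 6.7 days, a plausible gated cell cycle).
MCMC operates on the unconstrained scale — logit for the Beta-supported
parameters, log for the LogNormal-supported — with the exact log-Jacobian
of the inverse transform entering the acceptance ratio.

## Synthetic data

The reference dataset is a single model draw at
`θ = (0.2, 10⁻⁵, 31, 114)`. No extra observation noise is added: the
series carries only the model's intrinsic stochasticity. The generator
emulates the shape of caliper growth-curve data — noisy, monotone-trending
volumes on a regular measurement grid — but not several features of real
in-vivo series: measurement error of hand-held calipers, inter-animal
heterogeneity, 3-D geometry projected to two caliper axes, and possible
treatment or regression phases. Passing recovery tests on this generator
therefore demonstrates correctness of the inference machinery under the
model, not robustness to the misspecification that real tumour data would
introduce.

## Distance

`‖x − y‖` is the Euclidean norm between `log(volume + 1)` vectors on the
shared day grid. The log transform stops the late, large volumes from
dominating the norm; `+1` keeps zero volumes finite. A raw-volume
Euclidean metric ships as an alternative (`metric="raw"`). Series are
compared directly at matched days without a summary statistic.

## SMC-ABC engine

Adaptive replenishment scheme: initialise N particles from the prior
(ε₀ = largest distance); then repeatedly set ε to the α-quantile of the
current distances (lower/inverse-ecdf convention, so exactly `ceil(αN)`
particles survive — this also makes the degenerate zero-survivor case
impossible), resample the survivors back up to N uniformly with
replacement, and move each resampled particle with MH steps targeting the
ABC posterior at the current ε. Defaults: N = 100, α = 0.5.

The MH proposal is a Gaussian random walk on the unconstrained scale with
covariance `(2.38²/d) × (empirical particle covariance)` plus `1e-8`
diagonal jitter (diagonal-variance fallback if singular). The prior ×
Jacobian ratio is evaluated first and the simulation is run only when that
ratio passes, which saves budget without changing the stationary
distribution (the factorised acceptance probability is identical). The
number of MH repeats per iteration is `ceil(log c / log(1 − acc))` with
`c = 0.01`, capped (default 10), using the previous iteration's acceptance
rate (initial guess 0.5). Stopping: ε below a target, acceptance rate
below `min_acceptance = 0.01` (the regime where ABC-MCMC becomes
impractical), or the simulation budget spent.

Reproducibility: every simulation stream is seeded from
`(global seed, iteration, particle index)` via `numpy` `SeedSequence`, and
prior draws / resampling use dedicated master streams, so reruns are
bit-identical and per-particle simulation could be parallelised without
changing results.

## Posterior predictive

Bands are pointwise quantiles (default 2.5/50/97.5%) of `n_draws`
re-simulations at parameters drawn uniformly with replacement from the
final particles — fresh noise, not the stored particle series, so the
bands measure the full predictive distribution. "Tight enclosure" of the
data is quantified as the fraction of observed points inside the band,
with a 0.9 target under the 95% band. Two caveats apply to this statistic
on a single short series. First, pointwise 95% bands miss ~5% of points
even under perfect calibration. Second, with one fixed reference draw the
misses are systematic rather than averaged away: in the bundled
desk-scale study the reference's enrolment volume happens to lie in the
lower ~2% tail of the (parameter-free) initial-condition noise, and every
pre-growth measurement (days 0–4, before the ~114 h age gate opens) is a
correlated copy of that tail draw. Those 2–3 of the 8 points sit below
the band in every replicate, capping measured coverage near 0.75–0.88
whatever the simulation budget, while every parameter-dependent
(post-onset) point is enclosed in every replicate. The bundled coverage
check states the 0.9 target literally and currently fails for exactly
this reason; the honest remedies — conditioning the simulator's initial
state on the enrolment measurement, or scoring only post-enrolment
points — would change the model contract and the statistic respectively,
so neither is applied silently. This is the main known limitation of
operationalising "tight enclosure" as pointwise band coverage of an
unconditioned short series.

## Problem sizes

Two profiles ship. The *reference* profile mirrors a caliper study design:
32 days measured every 2 days, `dt = 1 h`, tumour radius 3 with a width-15
healthy annulus (~1200 cells; ≈ 10 s per simulation). The *desk* profile,
used by the bundled recovery study, the acceptance script and the heavier
tests, is chosen so that a full 10-replicate calibration study runs in
minutes on one CPU: 14 days measured every 2 days, `dt = 3 h` (η rescaled
so the per-step mobility stays 0.1), radius 3, width-4 annulus,
`max_cells = 800`, and an SMC budget of 400 simulations per run
(initialisation plus roughly three tolerance drops, final ε ≈ 0.3–0.4 in
log-volume units). These sizes are deliberate scale reductions of the same
model and sampler; nothing in the method depends on them.

## Identifiability: what recovery does and does not show

With data generated at `θ = (0.2, 10⁻⁵, 31, 114)`:

* `g_age` is sharply identified (the growth-onset time and inter-doubling
  period are direct functions of it); desk-scale posteriors concentrate
  near 114 h.
* `p_0` is structurally weak: the cell cycle is `g_age + O(dt/p_0)`, so
  over most of the prior the distance between simulated and observed
  series is flat in `p_0` at the intrinsic noise floor. Posteriors exclude
  very small `p_0` but otherwise stay close to the uniform prior; credible
  intervals cover the generating value, and no point estimate of `p_0`
  should be expected to concentrate near it from a single volume series at
  any simulation budget.
* `p_psc` at 10⁻⁵ and `d_max` larger than the tumour radius are nearly
  inert over the simulated horizon and remain prior-dominated.

The recovery study therefore checks credible-interval containment (a
calibration property the sampler should deliver for identified and
unidentified directions alike), not point-estimate accuracy.

## Known limitations

* 2-D only; caliper volumes from 2-D clouds are internally consistent but
  not comparable to mm³ without calibration.
* No cell death or quiescence; the model cannot represent tumour
  regression.
* The invasion mechanism is one reading of a loosely specified rule.
* The adaptive MH repeat count uses the previous iteration's acceptance
  rate; a mid-iteration re-tune (as in some replenishment variants) would
  react faster when acceptance collapses.
* The command-line layer is a thin wrapper over the library; long
  reference-profile calibrations from the CLI are possible but are better
  driven through the Python API with custom budgets.
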