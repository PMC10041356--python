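"""Stochastic 2-D Voronoi cell-based model (VCBM) of tumour growth.

Cells (cancer and healthy) are point agents in the plane; each cell's
boundary is the Voronoi region of its centre, so neighbourhood structure is
the dual Delaunay triangulation.  Per timestep the model applies, in order:

1. invasion   — boundary cancer cells convert a random healthy Delaunay
                neighbour with probability ``ppsc``;
2. proliferation — cancer cells older than ``gage`` attempt division with
                probability ``p0 * (1 - d/dmax)`` where ``d`` is the
                distance to the nearest healthy cell centre;
3. mechanics  — overdamped Hookean spring relaxation along Delaunay edges,
                followed by a single adjacency rebuild.

Tumour volume is read off the cancer-cell point cloud with the caliper
convention used for xenografts: ``V = L * W**2 / 2`` with length and width
the extents along the principal axes, each padded by one cell diameter.

All lengths are in cell diameters, all times in hours unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = [
    "VCBMParams",
    "SimConfig",
    "TissueState",
    "TumourTimeSeries",
    "ConfigurationError",
    "GeometryError",
    "TerminalStateError",
    "NumericalStabilityError",
    "delaunay_adjacency",
    "init_tissue",
    "distance_to_boundary",
    "distances_to_boundary",
    "proliferation_probability",
    "mechanics_step",
    "proliferation_step",
    "invasion_step",
    "measure_volume",
    "simulate",
    "pad_series",
]

CANCER = 1
HEALTHY = 0


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


class GeometryError(ValueError):
    """Degenerate geometry (too few or collinear points)."""


class TerminalStateError(RuntimeError):
    """Simulation reached a state with no healthy (or no cancer) cells."""


class NumericalStabilityError(RuntimeError):
    """Non-finite positions produced by a mechanics update."""


@dataclass(frozen=True)
class VCBMParams:
    """The four calibration parameters of the VCBM.

    Parameters
    ----------
    p0 : float
        Probability of division per proliferation attempt, in [0, 1].
    ppsc : float
        Probability per boundary cancer cell per timestep of an invasion
        event, in [0, 1].
    dmax : float
        Maximum distance (cell diameters) from the tumour boundary at which
        a cell can still proliferate; > 0.
    gage : float
        Minimum cell age (hours) before a proliferation attempt; > 0.
    """

    p0: float
    ppsc: float
    dmax: float
    gage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ConfigurationError(f"p0 must be in [0,1], got {self.p0}")
        if not (0.0 <= self.ppsc <= 1.0):
            raise ConfigurationError(f"ppsc must be in [0,1], got {self.ppsc}")
        if not self.dmax > 0:
            raise ConfigurationError(f"dmax must be > 0, got {self.dmax}")
        if not self.gage > 0:
            raise ConfigurationError(f"gage must be > 0, got {self.gage}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.ppsc, self.dmax, self.gage])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "VCBMParams":
        return cls(*(float(v) for v in theta))


@dataclass(frozen=True)
class SimConfig:
    """Simulator settings (everything the four calibration parameters do
    not cover).

    ``spring_constant * dt / damping`` is the per-step mobility of the
    explicit overdamped update; the default 0.1 keeps spring relaxation
    stable.
    """

    dt: float = 1.0                  # timestep, hours
    n_days: float = 32.0             # simulated duration, days
    measure_every: float = 2.0       # measurement cadence, days
    init_cancer_radius: float = 3.0  # initial tumour radius, cell diameters
    domain_pad: float = 15.0         # healthy annulus width, cell diameters
    spring_constant: float = 1.0
    rest_length: float = 1.0         # cell diameters
    damping: float = 10.0
    daughter_offset: float = 0.5     # daughter placement distance
    jitter: float = 0.05             # lattice jitter amplitude (fraction of spacing)
    max_cells: int = 50_000          # guard against runaway growth
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("dt", "n_days", "measure_every", "rest_length", "damping"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.init_cancer_radius <= 0:
            raise ConfigurationError("init_cancer_radius must be > 0")
        if self.domain_pad <= 0:
            raise ConfigurationError("domain_pad must be > 0")
        if self.jitter < 0:
            raise ConfigurationError("jitter must be >= 0")

    @property
    def steps_per_day(self) -> int:
        spd = 24.0 / self.dt
        if abs(spd - round(spd)) > 1e-9:
            raise ConfigurationError("dt must divide 24 hours evenly")
        return int(round(spd))

    @property
    def measure_every_steps(self) -> int:
        m = self.measure_every * self.steps_per_day
        if abs(m - round(m)) > 1e-9:
            raise ConfigurationError("measure_every must be a whole number of steps")
        return int(round(m))


@dataclass
class TissueState:
    """All cells at one instant plus their Delaunay adjacency.

    ``edges`` holds each undirected Delaunay edge once as a row (i, j) with
    i < j; indices refer to rows of ``positions``.
    """

    positions: np.ndarray   # (n, 2) float
    kind: np.ndarray        # (n,) uint8, CANCER or HEALTHY
    age: np.ndarray         # (n,) int64, timesteps since birth
    edges: np.ndarray       # (m, 2) int, undirected, i < j
    time: int = 0           # elapsed timesteps

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def n_cancer(self) -> int:
        return int(np.sum(self.kind == CANCER))

    @property
    def n_healthy(self) -> int:
        return int(np.sum(self.kind == HEALTHY))

    def neighbors(self, i: int) -> np.ndarray:
        """Sorted Delaunay neighbours of cell ``i``."""
        e = self.edges
        out = np.concatenate([e[e[:, 0] == i, 1], e[e[:, 1] == i, 0]])
        return np.sort(out)

    def copy(self) -> "TissueState":
        return TissueState(
            self.positions.copy(), self.kind.copy(), self.age.copy(),
            self.edges.copy(), self.time,
        )


@dataclass(frozen=True)
class TumourTimeSeries:
    """Caliper-style tumour-volume measurements on a day grid."""

    days: np.ndarray
    volumes: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)
        if days.shape != vols.shape or days.ndim != 1:
            raise ValueError("days and volumes must be equal-length 1-D arrays")
        if len(days) and np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(vols < 0):
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.days)


def pad_series(series: TumourTimeSeries, days: np.ndarray) -> TumourTimeSeries:
    """Extend a (possibly truncated) series onto a longer day grid by
    carrying the last observed volume forward.

    The existing days must be a prefix of ``days``.
    """
    days = np.asarray(days, dtype=float)
    k = len(series.days)
    if k > len(days) or not np.allclose(series.days, days[:k]):
        raise ValueError("series days are not a prefix of the target grid")
    if k == len(days):
        return series
    vols = np.concatenate([series.volumes, np.full(len(days) - k, series.volumes[-1])])
    return TumourTimeSeries(days, vols, truncated=series.truncated)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def delaunay_adjacency(positions: np.ndarray) -> np.ndarray:
    """Undirected edge set of the Delaunay triangulation of 2-D points.

    Returns an (m, 2) integer array, one row per edge, i < j, sorted
    lexicographically.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 3:
        raise GeometryError("need at least 3 points for a triangulation")
    try:
        tri = Delaunay(positions)
    except QhullError as err:
        raise GeometryError(f"degenerate point set: {err}") from err
    s = tri.simplices.astype(np.int64)
    pairs = np.concatenate([s[:, [0, 1]], s[:, [0, 2]], s[:, [1, 2]]])
    lo = pairs.min(axis=1)
    hi = pairs.max(axis=1)
    # dedup via scalar codes: much faster than unique(axis=0)
    codes = np.unique(lo * len(positions) + hi)
    edges = np.column_stack([codes // len(positions), codes % len(positions)])
    return edges


def init_tissue(config: SimConfig, rng: np.random.Generator) -> TissueState:
    """Initial condition: cancer disk inside a healthy annulus.

    Cells sit on a hexagonal lattice with unit spacing; a cell is cancer if
    its (unjittered) lattice point lies within ``init_cancer_radius`` of the
    origin and healthy if it lies in the surrounding annulus of width
    ``domain_pad``.  Positions are then jittered uniformly by
    ``config.jitter`` per coordinate.  All ages start at 0.
    """
    r_out = config.init_cancer_radius + config.domain_pad
    dy = math.sqrt(3.0) / 2.0
    jmax = int(math.ceil(r_out / dy)) + 1
    imax = int(math.ceil(r_out)) + 1
    pts = []
    for j in range(-jmax, jmax + 1):
        xoff = 0.5 * (j % 2)
        y = j * dy
        for i in range(-imax, imax + 1):
            pts.append((i + xoff, y))
    pts = np.array(pts)
    r = np.hypot(pts[:, 0], pts[:, 1])
    keep = r <= r_out
    pts, r = pts[keep], r[keep]
    kind = np.where(r <= config.init_cancer_radius, CANCER, HEALTHY).astype(np.uint8)
    if not np.any(kind == CANCER):
        raise ConfigurationError("init_cancer_radius too small: no cancer cells")
    if config.jitter > 0:
        pts = pts + rng.uniform(-config.jitter, config.jitter, size=pts.shape)
    age = np.zeros(len(pts), dtype=np.int64)
    edges = delaunay_adjacency(pts)
    return TissueState(pts, kind, age, edges, time=0)


def distances_to_boundary(state: TissueState) -> np.ndarray:
    """Distance from every cancer cell centre to the nearest healthy cell
    centre, in cancer-cell order (order of appearance in ``state``)."""
    healthy = state.positions[state.kind == HEALTHY]
    if len(healthy) == 0:
        raise TerminalStateError("no healthy cells left; boundary undefined")
    cancer = state.positions[state.kind == CANCER]
    tree = cKDTree(healthy)
    d, _ = tree.query(cancer)
    return d


def distance_to_boundary(cell_index: int, state: TissueState) -> float:
    """Euclidean distance from one cancer cell to the tumour boundary,
    defined as the nearest healthy cell centre."""
    if state.kind[cell_index] != CANCER:
        raise ValueError(f"cell {cell_index} is not a cancer cell")
    healthy = state.positions[state.kind == HEALTHY]
    if len(healthy) == 0:
        raise TerminalStateError("no healthy cells left; boundary undefined")
    diff = healthy - state.positions[cell_index]
    return float(np.min(np.hypot(diff[:, 0], diff[:, 1])))


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def proliferation_probability(d: float | np.ndarray, params: VCBMParams):
    """P = p0 * (1 - d/dmax), clamped to 0 for d >= dmax."""
    p = params.p0 * (1.0 - np.asarray(d, dtype=float) / params.dmax)
    return np.maximum(p, 0.0)[()] if np.isscalar(d) else np.maximum(p, 0.0)


def mechanics_step(state: TissueState, config: SimConfig) -> TissueState:
    """One explicit overdamped Hookean relaxation step.

    Each cell moves by ``(dt/damping) * sum_j k (|x_j - x_i| - L0) u_ij``
    over its Delaunay neighbours j, synchronously; adjacency is rebuilt
    from the new positions.
    """
    pos = state.positions
    i, j = state.edges[:, 0], state.edges[:, 1]
    dvec = pos[j] - pos[i]
    r = np.hypot(dvec[:, 0], dvec[:, 1])
    safe = np.where(r > 1e-12, r, 1.0)
    mobility = config.spring_constant * config.dt / config.damping
    # force on i points toward j when the spring is stretched
    f = (mobility * (r - config.rest_length) / safe)[:, None] * dvec
    f[r <= 1e-12] = 0.0
    disp = np.zeros_like(pos)
    np.add.at(disp, i, f)
    np.add.at(disp, j, -f)
    new_pos = pos + disp
    if not np.all(np.isfinite(new_pos)):
        raise NumericalStabilityError(
            f"non-finite positions after mechanics update (mobility={mobility})"
        )
    try:
        edges = delaunay_adjacency(new_pos)
    except GeometryError:
        # fewer than 3 cells or a (near-)collinear arrangement: keep the
        # spring network as given rather than failing the step
        edges = state.edges
    return TissueState(new_pos, state.kind.copy(), state.age.copy(), edges, state.time)


def proliferation_step(
    state: TissueState,
    params: VCBMParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> TissueState:
    """Age-gated stochastic division of cancer cells.

    Cancer cells with age >= gage (converted to timesteps) attempt division
    with probability ``p0 (1 - d/dmax)``; a successful mother places a
    daughter at ``daughter_offset`` in a uniform direction and both ages
    reset to 0.  Everyone else ages by one step.  Adjacency is NOT rebuilt
    here (one rebuild per timestep, in the mechanics step).
    """
    gage_steps = int(math.ceil(params.gage / config.dt))
    cancer_mask = state.kind == CANCER
    cancer_idx = np.flatnonzero(cancer_mask)
    eligible = state.age[cancer_idx] >= gage_steps

    new_age = state.age + 1
    daughters = []
    mothers = []
    if np.any(eligible):
        d = distances_to_boundary(state)  # in cancer order
        p = np.where(eligible, proliferation_probability(d, params), 0.0)
        divide = rng.random(len(cancer_idx)) < p
        mothers = cancer_idx[divide]
        if len(mothers):
            theta = rng.uniform(0.0, 2.0 * np.pi, size=len(mothers))
            offs = config.daughter_offset * np.column_stack(
                [np.cos(theta), np.sin(theta)]
            )
            daughters = state.positions[mothers] + offs
            new_age[mothers] = 0

    if len(mothers) == 0:
        return TissueState(
            state.positions.copy(), state.kind.copy(), new_age,
            state.edges, state.time,
        )
    n_new = len(mothers)
    positions = np.concatenate([state.positions, daughters])
    kind = np.concatenate([state.kind, np.full(n_new, CANCER, dtype=np.uint8)])
    age = np.concatenate([new_age, np.zeros(n_new, dtype=np.int64)])
    return TissueState(positions, kind, age, state.edges, state.time)


def invasion_step(
    state: TissueState, params: VCBMParams, rng: np.random.Generator
) -> TissueState:
    """Boundary cancer cells convert one random healthy Delaunay neighbour
    each with probability ``ppsc`` per timestep."""
    if params.ppsc == 0.0:
        return state
    i, j = state.edges[:, 0], state.edges[:, 1]
    ki, kj = state.kind[i], state.kind[j]
    # directed cancer -> healthy pairs
    mask_ij = (ki == CANCER) & (kj == HEALTHY)
    mask_ji = (kj == CANCER) & (ki == HEALTHY)
    src = np.concatenate([i[mask_ij], j[mask_ji]])
    dst = np.concatenate([j[mask_ij], i[mask_ji]])
    if len(src) == 0:
        return state
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    boundary, start = np.unique(src, return_index=True)
    counts = np.diff(np.append(start, len(src)))
    fire = rng.random(len(boundary)) < params.ppsc
    if not np.any(fire):
        return state
    pick = start + (rng.random(len(boundary)) * counts).astype(np.int64)
    targets = dst[pick[fire]]
    kind = state.kind.copy()
    age = state.age.copy()
    kind[targets] = CANCER
    age[targets] = 0
    return TissueState(state.positions.copy(), kind, age, state.edges, state.time)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_volume(state: TissueState) -> float:
    """Caliper-style tumour volume of the cancer-cell point cloud.

    Length L and width W are the extents along the two principal axes of
    the cloud, each padded by one cell diameter to account for finite cell
    size; volume = L * W^2 / 2 with L >= W (the standard xenograft
    approximation from two perpendicular caliper readings).
    """
    pts = state.positions[state.kind == CANCER]
    if len(pts) == 0:
        raise TerminalStateError("no cancer cells; volume undefined")
    if len(pts) == 1:
        ext = np.zeros(2)
    else:
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered
        _, vecs = np.linalg.eigh(cov)
        proj = centered @ vecs
        ext = proj.max(axis=0) - proj.min(axis=0)
    padded = np.sort(ext + 1.0)
    w, length = padded[0], padded[1]
    return float(length * w * w / 2.0)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def simulate(
    params: VCBMParams,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> TumourTimeSeries:
    """Run the VCBM and return the caliper-volume time series.

    Per timestep: invasion -> proliferation -> mechanics (which rebuilds
    adjacency once).  Volume is recorded at day 0 and every
    ``measure_every`` days.  If the healthy tissue is exhausted, or the
    cell count exceeds ``config.max_cells`` (runaway growth far outside
    the observable regime), the series is truncated at the last completed
    measurement and flagged; callers needing fixed-length vectors pad with
    :func:`pad_series`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    state = init_tissue(config, rng)
    every = config.measure_every_steps
    n_steps = int(round(config.n_days * config.steps_per_day))
    days, volumes = [0.0], [measure_volume(state)]
    truncated = False
    for step in range(1, n_steps + 1):
        try:
            state = invasion_step(state, params, rng)
            state = proliferation_step(state, params, config, rng)
            state = mechanics_step(state, config)
        except TerminalStateError:
            truncated = True
            break
        if state.n_cells > config.max_cells:
            truncated = True
            break
        state.time = step
        if step % every == 0:
            days.append(step / config.steps_per_day)
            volumes.append(measure_volume(state))
    return TumourTimeSeries(np.array(days), np.array(volumes), truncated=truncated)
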