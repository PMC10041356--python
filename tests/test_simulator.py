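"""Unit and property tests for the tumour-growth simulator."""

import math

import numpy as np
import pytest

from vcbm_abc.simulator import (
    CANCER,
    HEALTHY,
    GeometryError,
    SimConfig,
    TerminalStateError,
    TissueState,
    TumourTimeSeries,
    VCBMParams,
    delaunay_adjacency,
    distance_to_boundary,
    distances_to_boundary,
    init_tissue,
    invasion_step,
    measure_volume,
    mechanics_step,
    pad_series,
    proliferation_probability,
    proliferation_step,
    simulate,
)

THETA_REF = VCBMParams(0.2, 1e-5, 31.0, 114.0)


def make_state(positions, kinds, ages=None):
    positions = np.asarray(positions, dtype=float)
    kinds = np.asarray(kinds, dtype=np.uint8)
    ages = (
        np.zeros(len(positions), dtype=np.int64)
        if ages is None
        else np.asarray(ages, dtype=np.int64)
    )
    if len(positions) >= 3:
        edges = delaunay_adjacency(positions)
    else:
        edges = np.array([[0, 1]]) if len(positions) == 2 else np.empty((0, 2), int)
    return TissueState(positions, kinds, ages, edges)


# ---------------------------------------------------------------------------
# params / series containers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "bad",
    [
        dict(p0=-0.1, ppsc=0, dmax=1, gage=1),
        dict(p0=1.1, ppsc=0, dmax=1, gage=1),
        dict(p0=0.5, ppsc=2, dmax=1, gage=1),
        dict(p0=0.5, ppsc=0, dmax=0, gage=1),
        dict(p0=0.5, ppsc=0, dmax=1, gage=0),
    ],
)
def test_params_validation(bad):
    with pytest.raises(ValueError):
        VCBMParams(**bad)


def test_series_validation():
    with pytest.raises(ValueError):
        TumourTimeSeries([0, 2, 2], [1, 1, 1])
    with pytest.raises(ValueError):
        TumourTimeSeries([0, 2], [1, -1])
    with pytest.raises(ValueError):
        TumourTimeSeries([0, 2], [1, 2, 3])


def test_pad_series_carries_last_volume_forward():
    s = TumourTimeSeries([0.0, 2.0], [1.0, 5.0], truncated=True)
    grid = np.array([0.0, 2.0, 4.0, 6.0])
    padded = pad_series(s, grid)
    assert np.allclose(padded.volumes, [1.0, 5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        pad_series(s, np.array([0.0, 1.0, 2.0]))


# ---------------------------------------------------------------------------
# initial condition and triangulation
# ---------------------------------------------------------------------------

def test_init_tissue_cancer_count_matches_lattice_enumeration(rng):
    # independent enumeration of hexagonal lattice points within radius 5
    cfg = SimConfig(init_cancer_radius=5.0, domain_pad=3.0, jitter=0.0)
    state = init_tissue(cfg, rng)
    dy = math.sqrt(3.0) / 2.0
    count = 0
    for j in range(-10, 11):
        for i in range(-10, 11):
            x, y = i + 0.5 * (j % 2), j * dy
            if x * x + y * y <= 25.0 + 1e-12:
                count += 1
    assert state.n_cancer == count


def test_init_tissue_every_cancer_cell_sees_healthy_tissue(rng):
    cfg = SimConfig(init_cancer_radius=1.0, domain_pad=3.0)
    state = init_tissue(cfg, rng)
    assert state.n_cancer >= 1 and state.n_healthy >= 1
    d = distances_to_boundary(state)
    assert np.all(d < 1.0 + 3.0)


def test_init_tissue_rejects_bad_geometry(rng):
    with pytest.raises(ValueError):
        SimConfig(domain_pad=0.0)
    with pytest.raises(ValueError):
        SimConfig(init_cancer_radius=-1.0)


def test_delaunay_triangle_and_square():
    tri = delaunay_adjacency(np.array([[0, 0], [1, 0], [0, 1]]))
    assert tri.tolist() == [[0, 1], [0, 2], [1, 2]]
    square = delaunay_adjacency(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
    assert len(square) == 5  # 4 sides + 1 diagonal


def test_delaunay_errors_on_degenerate_input():
    with pytest.raises(GeometryError):
        delaunay_adjacency(np.array([[0, 0], [1, 1]]))
    with pytest.raises(GeometryError):
        delaunay_adjacency(np.column_stack([np.arange(5.0), np.arange(5.0)]))


def test_delaunay_matches_independent_triangulation_oracle(rng):
    # matplotlib ships its own C++ Delaunay implementation, independent of
    # the Qhull-backed one used by the simulator
    from matplotlib.tri import Triangulation

    pts = rng.random((50, 2))
    ours = {tuple(e) for e in delaunay_adjacency(pts)}
    theirs = {tuple(sorted(e)) for e in Triangulation(pts[:, 0], pts[:, 1]).edges}
    assert ours == theirs


def test_adjacency_symmetric_irreflexive(tiny_state):
    edges = tiny_state.edges
    assert np.all(edges[:, 0] < edges[:, 1])
    n9 = tiny_state.neighbors(9)
    assert 9 not in n9
    for j in n9:
        assert 9 in tiny_state.neighbors(int(j))


# ---------------------------------------------------------------------------
# boundary distance and proliferation rule
# ---------------------------------------------------------------------------

def test_distance_to_boundary_unit_and_degenerate():
    st = make_state([[0, 0], [0, 1], [5, 5]], [CANCER, HEALTHY, HEALTHY])
    assert distance_to_boundary(0, st) == pytest.approx(1.0)
    # coincident cancer and healthy centres: distance degenerates to zero
    st2 = TissueState(
        np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 1.0]]),
        np.array([CANCER, HEALTHY, HEALTHY], dtype=np.uint8),
        np.zeros(3, np.int64),
        np.empty((0, 2), int),
    )
    assert distance_to_boundary(0, st2) == pytest.approx(0.0)


def test_distance_to_boundary_matches_exhaustive_scan(rng):
    pts = rng.random((100, 2)) * 20
    kinds = (rng.random(100) < 0.5).astype(np.uint8)
    kinds[:2] = [CANCER, HEALTHY]  # ensure both present
    st = make_state(pts, kinds)
    d = distances_to_boundary(st)
    healthy = pts[kinds == HEALTHY]
    for k, i in enumerate(np.flatnonzero(kinds == CANCER)):
        brute = np.min(np.linalg.norm(healthy - pts[i], axis=1))
        assert d[k] == pytest.approx(brute)
        assert distance_to_boundary(int(i), st) == pytest.approx(brute)


def test_distance_requires_healthy_cells():
    st = make_state([[0, 0], [1, 0], [0, 1]], [CANCER, CANCER, CANCER])
    with pytest.raises(TerminalStateError):
        distance_to_boundary(0, st)


@pytest.mark.parametrize(
    "d, expected",
    [
        (0.0, 0.2),            # boundary cell divides at the full rate p0
        (31.0, 0.0),           # at dmax the rate vanishes
        (15.5, 0.1),           # linear midpoint
        (40.0, 0.0),           # beyond dmax: clamped, not negative
    ],
)
def test_proliferation_probability(d, expected):
    assert proliferation_probability(d, THETA_REF) == pytest.approx(expected)


def test_proliferation_probability_bounded_in_0_p0(rng):
    d = rng.uniform(0, 100, size=500)
    p = proliferation_probability(d, THETA_REF)
    assert np.all((p >= 0) & (p <= THETA_REF.p0))


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------

def test_mechanics_two_cells_at_rest_length_do_not_move():
    cfg = SimConfig(init_cancer_radius=1, domain_pad=1)
    st = make_state([[0, 0], [1, 0]], [CANCER, HEALTHY])
    out = mechanics_step(st, cfg)
    assert np.allclose(out.positions, st.positions)


def test_mechanics_compressed_pair_moves_apart_symmetrically():
    cfg = SimConfig(init_cancer_radius=1, domain_pad=1)
    st = make_state([[0, 0], [0.5, 0]], [CANCER, HEALTHY])
    out = mechanics_step(st, cfg)
    disp = out.positions - st.positions
    assert disp[0, 0] < 0 and disp[1, 0] > 0
    assert np.allclose(disp[0], -disp[1])
    assert np.allclose(disp[:, 1], 0)


def test_mechanics_chain_relaxes_to_rest_length():
    cfg = SimConfig(init_cancer_radius=1, domain_pad=1)
    pos = np.column_stack([np.linspace(0.0, 10.8, 10), np.zeros(10)])
    edges = np.column_stack([np.arange(9), np.arange(1, 10)])
    st = TissueState(pos, np.ones(10, np.uint8), np.zeros(10, np.int64), edges)
    for _ in range(3000):
        st = mechanics_step(st, cfg)
    spacings = np.diff(st.positions[:, 0])
    assert np.all(np.abs(spacings - cfg.rest_length) < 1e-3)


def test_mechanics_conserves_momentum(tiny_state, tiny_config):
    out = mechanics_step(tiny_state, tiny_config)
    total = (out.positions - tiny_state.positions).sum(axis=0)
    assert np.all(np.abs(total) < 1e-9)


def test_mechanics_rebuilds_adjacency(tiny_state, tiny_config):
    out = mechanics_step(tiny_state, tiny_config)
    assert np.array_equal(out.edges, delaunay_adjacency(out.positions))


# ---------------------------------------------------------------------------
# proliferation and invasion
# ---------------------------------------------------------------------------

def test_proliferation_age_gate(tiny_state, tiny_config, rng):
    out = proliferation_step(tiny_state, THETA_REF, tiny_config, rng)
    assert out.n_cells == tiny_state.n_cells  # everyone younger than gage
    assert np.array_equal(out.age, tiny_state.age + 1)


def test_proliferation_zero_rate(tiny_state, tiny_config, rng):
    st = tiny_state.copy()
    st.age[:] = 10_000
    out = proliferation_step(st, VCBMParams(0.0, 0.0, 31, 114), tiny_config, rng)
    assert out.n_cells == st.n_cells


def test_proliferation_certain_division_doubles_count(tiny_config, rng):
    # p0=1 with an effectively infinite dmax: every eligible cell divides,
    # so the cancer count doubles exactly
    params = VCBMParams(1.0, 0.0, 1e9, tiny_config.dt)
    means = []
    for _ in range(50):
        st = init_tissue(tiny_config, rng)
        st.age[:] = 10
        out = proliferation_step(st, params, tiny_config, rng)
        means.append(out.n_cancer / st.n_cancer)
    assert np.allclose(means, 2.0)


def test_proliferation_binomial_expectation(tiny_config, rng):
    # p0=0.5 at huge dmax: divisions ~ Binomial(n_cancer, ~0.5)
    params = VCBMParams(0.5, 0.0, 1e9, tiny_config.dt)
    st0 = init_tissue(tiny_config, rng)
    st0.age[:] = 10
    n = st0.n_cancer
    d = distances_to_boundary(st0)
    p = 0.5 * (1 - d / 1e9)
    reps = 400
    counts = np.array([
        proliferation_step(st0, params, tiny_config, rng).n_cancer - n
        for _ in range(reps)
    ])
    expected = p.sum()
    se = math.sqrt(np.sum(p * (1 - p)) / reps)
    assert abs(counts.mean() - expected) < 3 * se


def test_proliferation_resets_mother_and_daughter_age(tiny_config, rng):
    params = VCBMParams(1.0, 0.0, 1e9, tiny_config.dt)
    st = init_tissue(tiny_config, rng)
    st.age[:] = 7
    out = proliferation_step(st, params, tiny_config, rng)
    assert np.all(out.age[out.kind == CANCER] == 0)
    assert np.all(out.age[out.kind == HEALTHY] == 8)


def test_invasion_zero_probability_is_identity(tiny_state, rng):
    out = invasion_step(tiny_state, VCBMParams(0.5, 0.0, 31, 114), rng)
    assert np.array_equal(out.kind, tiny_state.kind)


def test_invasion_forced_event_converts_exactly_one_neighbor(rng):
    # one cancer cell surrounded by 3 healthy neighbours, ppsc = 1
    st = make_state(
        [[0, 0], [1, 0], [-0.5, 0.9], [-0.5, -0.9]],
        [CANCER, HEALTHY, HEALTHY, HEALTHY],
    )
    out = invasion_step(st, VCBMParams(0.5, 1.0, 31, 114), rng)
    assert out.n_cancer == 2
    assert out.age[out.kind == CANCER].min() == 0


def test_invasion_single_cell_bernoulli_expectation():
    # one boundary cancer cell: conversions per step ~ Bernoulli(ppsc)
    params = VCBMParams(0.5, 0.3, 31, 114)
    st = make_state(
        [[0, 0], [1, 0], [-0.5, 0.9], [-0.5, -0.9]],
        [CANCER, HEALTHY, HEALTHY, HEALTHY],
    )
    reps = 2000
    rng = np.random.default_rng(5)
    conv = np.array([
        invasion_step(st, params, rng).n_cancer - 1 for _ in range(reps)
    ])
    se = math.sqrt(0.3 * 0.7 / reps)
    assert abs(conv.mean() - 0.3) < 3 * se


def test_invasion_many_cells_bounded_by_binomial_mean(tiny_state):
    # with many boundary cells, conversions are at most the number of
    # firing cells (several cells may pick the same healthy target)
    params = VCBMParams(0.5, 0.5, 31, 114)
    edges = tiny_state.edges
    ki, kj = tiny_state.kind[edges[:, 0]], tiny_state.kind[edges[:, 1]]
    boundary = set(edges[(ki == CANCER) & (kj == HEALTHY), 0]) | set(
        edges[(kj == CANCER) & (ki == HEALTHY), 1]
    )
    nb = len(boundary)
    assert nb > 0
    reps = 600
    rng = np.random.default_rng(5)
    conv = np.array([
        invasion_step(tiny_state, params, rng).n_cancer - tiny_state.n_cancer
        for _ in range(reps)
    ])
    expected_fire = 0.5 * nb
    se = math.sqrt(nb * 0.25 / reps)
    assert conv.mean() <= expected_fire + 3 * se
    assert conv.mean() > 0.4 * expected_fire


# ---------------------------------------------------------------------------
# volume measurement
# ---------------------------------------------------------------------------

def test_volume_single_cell_is_half():
    st = make_state([[3, 4], [10, 10], [11, 10]], [CANCER, HEALTHY, HEALTHY])
    assert measure_volume(st) == pytest.approx(0.5)


def test_volume_rectangle_with_padding():
    corners = [[0, 0], [4, 0], [0, 2], [4, 2]]
    st = make_state(corners, [CANCER] * 4)
    # L = 4+1, W = 2+1 -> 5 * 9 / 2
    assert measure_volume(st) == pytest.approx(22.5)


def test_volume_rotation_invariant(rng):
    pts = rng.random((40, 2)) * 6
    st = make_state(pts, [CANCER] * 40)
    v0 = measure_volume(st)
    phi = 0.7
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    st2 = make_state(pts @ R.T + 13.0, [CANCER] * 40)
    assert measure_volume(st2) == pytest.approx(v0, rel=1e-6)


def test_volume_requires_cancer_cells():
    st = make_state([[0, 0], [1, 0], [0, 1]], [HEALTHY] * 3)
    with pytest.raises(TerminalStateError):
        measure_volume(st)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def test_simulate_frozen_dynamics_keeps_volume_constant():
    cfg = SimConfig(dt=1.0, n_days=2.0, measure_every=1.0,
                    init_cancer_radius=3, domain_pad=5, jitter=0.0)
    s = simulate(VCBMParams(0.0, 0.0, 31, 114), cfg, np.random.default_rng(0))
    # springs still relax the rim of the finite disk a little
    assert np.all(np.abs(s.volumes / s.volumes[0] - 1) < 0.02)
    cfg0 = SimConfig(dt=1.0, n_days=2.0, measure_every=1.0, spring_constant=0.0,
                     init_cancer_radius=3, domain_pad=5, jitter=0.0)
    s0 = simulate(VCBMParams(0.0, 0.0, 31, 114), cfg0, np.random.default_rng(0))
    assert np.allclose(s0.volumes, s0.volumes[0])


def test_simulate_deterministic_given_seed(tiny_config):
    a = simulate(THETA_REF, tiny_config, np.random.default_rng(11))
    b = simulate(THETA_REF, tiny_config, np.random.default_rng(11))
    assert np.array_equal(a.volumes, b.volumes) and np.array_equal(a.days, b.days)


def test_simulate_growth_regime(tiny_config):
    # at the reference parameters the tumour grows in nearly every replicate
    cfg = SimConfig(dt=3.0, damping=30.0, n_days=14.0, measure_every=2.0,
                    init_cancer_radius=3.0, domain_pad=4.0, max_cells=800)
    grew = sum(
        (lambda s: s.volumes[-1] > s.volumes[0])(
            simulate(THETA_REF, cfg, np.random.default_rng(seed))
        )
        for seed in range(20)
    )
    assert grew >= 19


def test_simulate_series_length_and_grid(tiny_config):
    s = simulate(THETA_REF, tiny_config, np.random.default_rng(3))
    n_expected = int(tiny_config.n_days // tiny_config.measure_every) + 1
    assert len(s) == n_expected
    assert np.allclose(np.diff(s.days), tiny_config.measure_every)


def test_simulate_cancer_count_never_decreases(tiny_config, rng):
    params = VCBMParams(0.3, 1e-3, 1e9, 3.0)
    st = init_tissue(tiny_config, rng)
    prev = st.n_cancer
    for _ in range(12):
        st = invasion_step(st, params, rng)
        st = proliferation_step(st, params, tiny_config, rng)
        st = mechanics_step(st, tiny_config)
        assert st.n_cancer >= prev
        prev = st.n_cancer


def test_branching_oracle_doubles_per_generation(rng):
    # p0=1, huge dmax, one-step age gate, springs off: every generation
    # (gate step + division step under the age-reset convention) the cancer
    # population doubles, matching the branching oracle 2^g * n0
    cfg = SimConfig(dt=3.0, n_days=4, measure_every=2.0, spring_constant=0.0,
                    init_cancer_radius=2.0, domain_pad=3.0, max_cells=10_000)
    params = VCBMParams(1.0, 0.0, 1e12, cfg.dt)
    st = init_tissue(cfg, rng)
    n0 = st.n_cancer
    st.age[:] = 1
    for g in range(1, 4):
        st = proliferation_step(st, params, cfg, rng)   # everyone divides
        assert st.n_cancer == n0 * 2**g
        st = proliferation_step(st, params, cfg, rng)   # newborns gate
        assert st.n_cancer == n0 * 2**g
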