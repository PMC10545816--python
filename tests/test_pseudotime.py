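"""Pseudotime: grid, streamlines, trajectory selection, time-zone merging."""

import numpy as np
import pytest

from velorelay import EmbeddingVelocity, TimeZoneCycleError
from velorelay.pseudotime import (
    LongTrajectorySet,
    adjust_time_zones,
    assign_pseudotime,
    build_grid,
    estimate_pseudotime,
    select_long_trajectories,
    trace_trajectories,
)


def _emb(coords, vel):
    return EmbeddingVelocity(coords=np.asarray(coords, float),
                             vel2d=np.asarray(vel, float))


# ---------------------------------------------------------------------------
# grid


def test_grid_bin_means_match_bruteforce(rng):
    coords = rng.random((100, 2))
    vel = rng.normal(size=(100, 2))
    grid = build_grid(_emb(coords, vel), grid_shape=(5, 5))
    for ix in range(5):
        for iy in range(5):
            members = np.flatnonzero((grid.cell_bins[:, 0] == ix)
                                     & (grid.cell_bins[:, 1] == iy))
            if members.size:
                assert np.allclose(grid.bin_velocity[ix, iy], vel[members].mean(axis=0))
            else:
                assert np.allclose(grid.bin_velocity[ix, iy], 0.0)


def test_grid_opposite_velocities_cancel():
    coords = np.array([[0.1, 0.1], [0.15, 0.12], [0.9, 0.9]])
    vel = np.array([[1.0, 0.5], [-1.0, -0.5], [0.2, 0.2]])
    grid = build_grid(_emb(coords, vel), grid_shape=(2, 2))
    assert np.allclose(grid.bin_velocity[0, 0], 0.0)


def test_grid_degenerate_bounding_box():
    coords = np.tile([[0.5, 0.5]], (4, 1))
    with pytest.raises(ValueError):
        build_grid(_emb(coords, np.zeros((4, 2))), (3, 3))


# ---------------------------------------------------------------------------
# tracing


def test_zero_field_trajectories_are_points(rng):
    coords = rng.random((20, 2))
    grid = build_grid(_emb(coords, np.zeros((20, 2))), (4, 4))
    pool = trace_trajectories(grid, coords, n_steps=50, n_repeats=2, seed=0)
    assert all(len(p) == 1 for p in pool.positions)
    assert np.allclose(pool.traverse_lengths(), 0.0)


def test_constant_field_straight_path():
    # uniform rightward field, no sway: straight path of n_steps segments
    coords = np.array([[0.05, 0.45], [0.1, 0.5], [0.2, 0.55], [0.9, 0.5]])
    vel = np.tile([0.05, 0.0], (4, 1))
    grid = build_grid(_emb(coords, vel), (3, 3))
    pool = trace_trajectories(grid, coords[:1], dt=0.5, n_steps=10,
                              n_repeats=1, sway_sd=0.0, seed=1)
    path = pool.positions[0]
    assert len(path) > 2
    assert np.allclose(path[:, 1], path[0, 1])            # no vertical drift
    steps = np.diff(path[:, 0])
    assert np.allclose(steps, 0.05 * 0.5)
    expected_len = (len(path) - 1) * 0.05 * 0.5
    assert pool.traverse_lengths()[0] == pytest.approx(expected_len)


def test_tracing_stops_outside_grid():
    coords = np.array([[0.9, 0.5], [0.1, 0.5], [0.5, 0.1], [0.5, 0.9]])
    vel = np.tile([1.0, 0.0], (4, 1))  # strong rightward flow
    grid = build_grid(_emb(coords, vel), (3, 3))
    pool = trace_trajectories(grid, coords[:1], dt=1.0, n_steps=500,
                              n_repeats=1, sway_sd=0.0, seed=0)
    assert len(pool.positions[0]) < 10  # leaves the box quickly


def test_tracing_seeded_determinism(rng):
    coords = rng.random((30, 2))
    vel = rng.normal(scale=0.05, size=(30, 2))
    grid = build_grid(_emb(coords, vel), (5, 5))
    p1 = trace_trajectories(grid, coords, n_steps=40, n_repeats=3, seed=7)
    p2 = trace_trajectories(grid, coords, n_steps=40, n_repeats=3, seed=7)
    for a, b in zip(p1.positions, p2.positions):
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# long-trajectory selection


def _pool_from(paths, dt=0.5):
    from velorelay.pseudotime import TrajectoryPool

    return TrajectoryPool(positions=[np.asarray(p, float) for p in paths],
                          start_cell=np.arange(len(paths)), dt=dt,
                          n_repeats=1, sway_sd=0.0)


def test_pool_of_one_selected():
    pool = _pool_from([[[0, 0], [0.5, 0]]])
    sel = select_long_trajectories(pool, similarity_cutoff=0.1)
    assert len(sel.trajectories) == 1


def test_identical_trajectories_deduplicated():
    path = [[0, 0], [0.5, 0], [1.0, 0]]
    pool = _pool_from([path, path])
    sel = select_long_trajectories(pool, similarity_cutoff=0.05)
    assert len(sel.trajectories) == 1


def test_two_separated_paths_both_selected():
    a = [[0, 0], [1, 0], [2, 0]]
    b = [[0, 5], [1, 5], [2, 5]]
    jitter_a = [[0.01, 0.02], [1.01, 0.01], [2.0, 0.03]]
    pool = _pool_from([a, b, jitter_a])
    sel = select_long_trajectories(pool, similarity_cutoff=0.2)
    assert len(sel.trajectories) == 2


def test_n_path_caps_selection():
    paths = [[[0, i], [3, i]] for i in range(6)]
    pool = _pool_from(paths)
    sel = select_long_trajectories(pool, similarity_cutoff=0.1, n_path=2)
    assert len(sel.trajectories) == 2


# ---------------------------------------------------------------------------
# assignment


def test_cell_on_trajectory_gets_its_time():
    path = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    long_set = LongTrajectorySet(trajectories=[path],
                                 times=[np.arange(4) * 0.5],
                                 lengths=np.array([3.0]), similarity_cutoff=0.1)
    cells = np.array([[1.0, 0.05], [2.9, 0.0], [0.1, 0.0]])
    pool = _pool_from([[c, path[-1]] for c in cells])
    raw, cluster, flagged = assign_pseudotime(cells, long_set, pool, radius=0.5)
    assert np.allclose(raw, [0.5, 1.5, 0.0])
    assert not flagged.any()
    # raw times are monotone in arc position
    order = np.argsort(cells[:, 0])
    assert np.all(np.diff(raw[order]) >= 0)


def test_unreachable_cell_flagged():
    path = np.array([[0.0, 0.0], [1.0, 0.0]])
    long_set = LongTrajectorySet(trajectories=[path], times=[np.array([0.0, 0.5])],
                                 lengths=np.array([1.0]), similarity_cutoff=0.1)
    cells = np.array([[50.0, 50.0]])
    pool = _pool_from([[[50.0, 50.0], [50.0, 51.0]]])
    raw, cluster, flagged = assign_pseudotime(cells, long_set, pool, radius=0.5)
    assert flagged[0]
    assert cluster[0] == 0


# ---------------------------------------------------------------------------
# time-zone adjustment


def test_single_cluster_rescaled_only():
    raw = np.array([2.0, 4.0, 6.0])
    adj, tau = adjust_time_zones(raw, np.zeros(3, int), shifts={})
    assert np.allclose(adj, [0.0, 0.5, 1.0])


def test_two_cluster_shift():
    raw = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
    cluster = np.array([0, 0, 0, 1, 1, 1])
    # overlap says zone-0 times are 5 units ahead of zone-1 times
    adj, tau = adjust_time_zones(raw, cluster, shifts={(0, 1): 5.0})
    assert tau[1] == pytest.approx(5.0)
    merged = raw + np.array([tau[c] for c in cluster])
    assert np.allclose(adj, (merged - merged.min()) / np.ptp(merged))
    # within-cluster order preserved (rigid shift)
    assert np.all(np.diff(adj[:3]) > 0) and np.all(np.diff(adj[3:]) > 0)


def test_chain_accumulates_shifts():
    raw = np.zeros(3)
    cluster = np.array([0, 1, 2])
    adj, tau = adjust_time_zones(raw, cluster, shifts={(0, 1): 2.0, (1, 2): 3.0})
    assert tau[1] == pytest.approx(2.0)
    assert tau[2] == pytest.approx(5.0)   # accumulated through the chain


def test_triangle_cycle_fails():
    raw = np.zeros(3)
    cluster = np.array([0, 1, 2])
    with pytest.raises(TimeZoneCycleError, match="n_path"):
        adjust_time_zones(raw, cluster,
                          shifts={(0, 1): 1.0, (1, 2): 1.0, (0, 2): 2.0})


def test_adjusted_time_in_unit_interval(rng):
    raw = rng.random(50) * 10
    cluster = rng.integers(0, 3, 50)
    adj, _ = adjust_time_zones(raw, cluster, shifts={(0, 1): 1.5, (1, 2): -0.5})
    assert adj.min() == pytest.approx(0.0)
    assert adj.max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# end to end


def test_pseudotime_tracks_simulation_time():
    """On a synthetic rightward flow, pseudotime increases with position."""
    rng = np.random.default_rng(0)
    n = 300
    x = rng.uniform(0, 1, n)
    y = rng.uniform(0, 0.2, n)
    coords = np.column_stack([x, y])
    vel = np.tile([0.05, 0.0], (n, 1)) + rng.normal(0, 0.002, (n, 2))
    emb = EmbeddingVelocity(coords=coords, vel2d=vel)
    pt, cluster, raw, flagged, long_set = estimate_pseudotime(
        emb, grid_shape=(10, 4), n_steps=100, n_repeats=4,
        similarity_cutoff=0.5, n_path=2, seed=0)
    from scipy.stats import spearmanr

    rho = spearmanr(x, pt).statistic
    assert rho > 0.8


def test_pseudotime_positive_on_simulated_loop():
    """Full projection + pseudotime on a simulated two-step gene set:
    the derived pseudotime correlates positively with simulation time.

    Uses 1,200 cells: the orientation statistics are neighborhood
    averages and need reasonably dense portraits.
    """
    from scipy.stats import spearmanr

    from velorelay import DatasetContainer, RegimeSpec, RunConfig, generate_dataset, run_pipeline
    from velorelay.benchmark import smooth_dataset

    ds = generate_dataset(RegimeSpec("mono_kinetic", n_cells=1200, n_genes=6, seed=0))
    su, ss = smooth_dataset(ds, 50)
    container = DatasetContainer(
        unspliced=ds.u, spliced=ds.s, cell_ids=ds.cell_ids,
        gene_names=ds.gene_names,
        embedding=np.column_stack([ss[:, 0], su[:, 0]]),
    )
    config = RunConfig(seed=0, smooth_n=50, projection_k=50,
                       grid_shape=(10, 10), n_steps=80, n_repeats=4, n_path=2)
    import tempfile

    with tempfile.TemporaryDirectory() as out:
        bundle = run_pipeline(config, container, out)
    pt = bundle["pseudotime_table"]["pseudotime"].to_numpy()
    rho = spearmanr(ds.time, pt).statistic
    assert rho > 0.3
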