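"""Gene-shared pseudotime from projected velocity streamlines.

The embedding is divided into a rectangular grid of "meta cells" whose
velocity is the mean projected velocity of the enclosed cells.  From every
cell a bundle of stochastic streamlines is traced through the grid field
(equation of motion ``xi(t + dt) = xi(t) + v_grid dt`` with a Gaussian
swaying angle ``N(0, pi/6)`` applied at every step).  Representative
"long trajectories" — local maxima of traverse length — are selected
greedily, each cell is assigned to the long trajectory its streamlines
terminate around, and its raw pseudotime is the time coordinate of the
closest point of that trajectory.  Finally the per-trajectory "time
zones" are merged on a cluster graph by median time shifts between
overlapping cells and rescaled to [0, 1].  A cyclic cluster graph is a
hard failure (reduce ``n_path``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .projection import EmbeddingVelocity

__all__ = [
    "MetaCellGrid",
    "TrajectoryPool",
    "LongTrajectorySet",
    "build_grid",
    "trace_trajectories",
    "select_long_trajectories",
    "assign_pseudotime",
    "adjust_time_zones",
    "estimate_pseudotime",
    "TimeZoneCycleError",
]

DEFAULT_SWAY_SD = math.pi / 6


class TimeZoneCycleError(RuntimeError):
    """Raised when the cluster graph of time zones contains a cycle."""


@dataclass
class MetaCellGrid:
    """Uniform rectangular binning of the embedding with mean bin velocity."""

    shape: tuple
    mins: np.ndarray
    bin_size: np.ndarray
    cell_bins: np.ndarray          # cells x 2 integer bin coordinates
    bin_velocity: np.ndarray       # nx x ny x 2, zero where empty

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.bin_size))

    def locate(self, points: np.ndarray):
        """Bin coordinates of arbitrary points plus an in-bounds mask."""
        ij = np.floor((points - self.mins) / self.bin_size).astype(int)
        nx, ny = self.shape
        inside = (
            (ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
        )
        return ij, inside


@dataclass
class TrajectoryPool:
    """Traced streamlines: one bundle of ``n_repeats`` per starting cell."""

    positions: list                 # list of (L_i, 2) arrays
    start_cell: np.ndarray          # walker -> starting cell index
    dt: float
    n_repeats: int
    sway_sd: float

    def traverse_lengths(self) -> np.ndarray:
        return np.array([
            float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()) if len(p) > 1 else 0.0
            for p in self.positions
        ])


@dataclass
class LongTrajectorySet:
    """Greedily selected representative trajectories with per-point times."""

    trajectories: list              # list of (L, 2) arrays
    times: list                     # list of (L,) arrays
    lengths: np.ndarray
    similarity_cutoff: float


def build_grid(emb: EmbeddingVelocity, grid_shape=(30, 30)) -> MetaCellGrid:
    """Bin cells into a uniform grid; bin velocity is the members' mean."""
    coords = emb.coords
    nx, ny = grid_shape
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    span = maxs - mins
    if np.any(span <= 0):
        raise ValueError("degenerate bounding box: all cells coincide on an axis")
    bin_size = span / np.array([nx, ny])
    ij = np.minimum(np.floor((coords - mins) / bin_size).astype(int), [nx - 1, ny - 1])
    vel = np.zeros((nx, ny, 2))
    counts = np.zeros((nx, ny))
    np.add.at(vel, (ij[:, 0], ij[:, 1]), emb.vel2d)
    np.add.at(counts, (ij[:, 0], ij[:, 1]), 1.0)
    occupied = counts > 0
    vel[occupied] /= counts[occupied][:, None]
    return MetaCellGrid(shape=(nx, ny), mins=mins, bin_size=bin_size,
                        cell_bins=ij, bin_velocity=vel)


def trace_trajectories(grid: MetaCellGrid, starts, dt: float = 0.5,
                       n_steps: int = 500, n_repeats: int = 10,
                       sway_sd: float = DEFAULT_SWAY_SD, seed: int = 0) -> TrajectoryPool:
    """Trace stochastic streamlines from every start position.

    At each step the current meta cell's velocity is rotated by an
    independent Gaussian angle and followed for ``dt``.  A walker stops
    after ``n_steps``, on leaving the grid, or in a zero-velocity bin.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    starts = np.asarray(starts, dtype=float)
    rng = np.random.default_rng(seed)
    n_walkers = starts.shape[0] * n_repeats
    pos = np.repeat(starts, n_repeats, axis=0).astype(float)
    start_cell = np.repeat(np.arange(starts.shape[0]), n_repeats)
    paths = [[p.copy()] for p in pos]
    active = np.ones(n_walkers, dtype=bool)

    for _ in range(n_steps):
        if not active.any():
            break
        ij, inside = grid.locate(pos[active])
        vel = np.zeros((ij.shape[0], 2))
        vel[inside] = grid.bin_velocity[ij[inside, 0], ij[inside, 1]]
        moving = inside & (np.linalg.norm(vel, axis=1) > 0)
        theta = rng.normal(0.0, sway_sd, size=ij.shape[0])
        c, s = np.cos(theta), np.sin(theta)
        rot = np.stack([c * vel[:, 0] - s * vel[:, 1],
                        s * vel[:, 0] + c * vel[:, 1]], axis=1)
        act_idx = np.flatnonzero(active)
        stopped = act_idx[~moving]
        stepped = act_idx[moving]
        pos[stepped] += rot[moving] * dt
        for w in stepped:
            paths[w].append(pos[w].copy())
        active[stopped] = False

    return TrajectoryPool(
        positions=[np.array(p) for p in paths],
        start_cell=start_cell,
        dt=dt,
        n_repeats=n_repeats,
        sway_sd=sway_sd,
    )


def _similarity(short: np.ndarray, tree: cKDTree) -> float:
    """Mean distance from each point of the shorter path to the other path."""
    d, _ = tree.query(short)
    return float(np.mean(d))


def select_long_trajectories(pool: TrajectoryPool, similarity_cutoff: float,
                             n_path: int | None = None) -> LongTrajectorySet:
    """Iteratively pick the longest trajectory, drop its look-alikes.

    Two trajectories are similar when the mean distance from each point of
    the shorter one to the nearest point of the longer one is within the
    cutoff.  Selection stops when the pool is exhausted, ``n_path``
    trajectories were selected, or only zero-length (stuck) trajectories
    remain after at least one selection.
    """
    lengths = pool.traverse_lengths()
    if len(pool.positions) == 0:
        raise ValueError("empty trajectory pool")
    remaining = list(np.argsort(-lengths, kind="stable"))
    selected, sel_times, sel_lengths = [], [], []
    while remaining:
        if n_path is not None and len(selected) >= n_path:
            break
        best = remaining[0]
        if lengths[best] <= 0 and selected:
            break
        traj = pool.positions[best]
        selected.append(traj)
        sel_times.append(np.arange(len(traj)) * pool.dt)
        sel_lengths.append(lengths[best])
        tree = cKDTree(traj)
        keep = []
        for idx in remaining[1:]:
            if _similarity(pool.positions[idx], tree) > similarity_cutoff:
                keep.append(idx)
        remaining = keep
    return LongTrajectorySet(
        trajectories=selected,
        times=sel_times,
        lengths=np.array(sel_lengths),
        similarity_cutoff=similarity_cutoff,
    )


def assign_pseudotime(cell_coords, long_set: LongTrajectorySet,
                      pool: TrajectoryPool, radius: float):
    """Per-cell raw pseudotime and trajectory cluster.

    A cell belongs to the long trajectory around which the majority of its
    traced repeats terminate (within ``radius``); its raw time is the time
    of the closest point of that trajectory to the cell's own position.
    Cells whose repeats reach no long trajectory fall back to the nearest
    one and are flagged.
    """
    cell_coords = np.asarray(cell_coords, dtype=float)
    n = cell_coords.shape[0]
    trees = [cKDTree(t) for t in long_set.trajectories]
    if not trees:
        raise ValueError("no long trajectories selected")

    terminals = np.array([p[-1] for p in pool.positions])
    # nearest long trajectory per terminal
    dists = np.column_stack([t.query(terminals)[0] for t in trees])
    nearest = dists.argmin(axis=1)
    within = dists[np.arange(len(terminals)), nearest] <= radius

    cluster = np.empty(n, dtype=int)
    raw_time = np.empty(n, dtype=float)
    flagged = np.zeros(n, dtype=bool)
    for j in range(n):
        walkers = np.flatnonzero(pool.start_cell == j)
        votes = nearest[walkers][within[walkers]]
        if votes.size:
            cluster[j] = np.bincount(votes, minlength=len(trees)).argmax()
        else:
            d_self = [t.query(cell_coords[j])[0] for t in trees]
            cluster[j] = int(np.argmin(d_self))
            flagged[j] = True
        _, pt = trees[cluster[j]].query(cell_coords[j])
        raw_time[j] = long_set.times[cluster[j]][pt]
    return raw_time, cluster, flagged


def _overlap_shifts(cell_coords, raw_time, cluster, k: int = 10):
    """Median time shifts between clusters from mutually-near cell pairs."""
    from .neighbors import knn_shared

    n = cell_coords.shape[0]
    kk = min(k, n - 1)
    graph = knn_shared(cell_coords, kk, mode="embedding")
    nbr = graph.indices
    is_nbr = np.zeros((n, n), dtype=bool)
    is_nbr[np.repeat(np.arange(n), kk), nbr.ravel()] = True
    mutual = is_nbr & is_nbr.T
    samples: dict = {}
    ii, jj = np.nonzero(np.triu(mutual, 1))
    for i, j in zip(ii, jj):
        cl, cm = cluster[i], cluster[j]
        if cl == cm:
            continue
        if cl > cm:
            i, j = j, i
            cl, cm = cm, cl
        samples.setdefault((cl, cm), []).append(raw_time[i] - raw_time[j])
    return {edge: float(np.median(vals)) for edge, vals in samples.items()}


def adjust_time_zones(raw_time, cluster, shifts) -> tuple:
    """Merge per-trajectory time zones and rescale to [0, 1].

    ``shifts`` maps ordered cluster pairs ``(l, m)`` with ``l < m`` to the
    median time difference ``t_l - t_m`` of their overlapping cells.  The
    cluster graph must be a forest; each tree is traversed from its
    lowest-id node accumulating shifts, every cluster's raw times receive
    its accumulated shift, and the result is min-max rescaled to [0, 1].
    Raises :class:`TimeZoneCycleError` on a cyclic graph.
    """
    raw_time = np.asarray(raw_time, dtype=float)
    cluster = np.asarray(cluster, dtype=int)
    nodes = sorted(set(cluster.tolist()) | {c for e in shifts for c in e})

    # union-find cycle detection while building adjacency
    parent = {c: c for c in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict = {c: [] for c in nodes}
    for (l, m), dt_lm in shifts.items():
        rl, rm = find(l), find(m)
        if rl == rm:
            raise TimeZoneCycleError(
                "cycle detected in the time-zone cluster graph; the time "
                "adjustment fails — we suggest reducing the n_path parameter"
            )
        parent[rl] = rm
        adj[l].append((m, dt_lm, +1))
        adj[m].append((l, dt_lm, -1))

    tau = {c: 0.0 for c in nodes}
    flag = {c: 0 for c in nodes}
    for root in nodes:               # lowest-id node of each tree first
        if flag[root]:
            continue
        flag[root] = 1
        stack = [root]
        while stack:
            o = stack.pop()
            for other, dt_lm, sign in adj[o]:
                if flag[other]:
                    continue
                # edge stored as (l, m) with shift t_l - t_m: walking from l
                # to m adds the shift, walking from m to l subtracts it
                tau[other] = tau[o] + sign * dt_lm
                flag[other] = 1
                stack.append(other)

    adjusted = raw_time + np.array([tau[c] for c in cluster])
    lo, hi = adjusted.min(), adjusted.max()
    if hi - lo > 0:
        adjusted = (adjusted - lo) / (hi - lo)
    else:
        adjusted = np.zeros_like(adjusted)
    return adjusted, tau


def estimate_pseudotime(emb: EmbeddingVelocity, grid_shape=(30, 30),
                        dt: float = 0.5, n_steps: int = 500, n_repeats: int = 10,
                        sway_sd: float = DEFAULT_SWAY_SD, n_path: int | None = None,
                        similarity_cutoff: float | None = None,
                        overlap_k: int = 10, seed: int = 0):
    """End-to-end gene-shared pseudotime for an embedded velocity field.

    Returns ``(pseudotime, cluster, raw_time, flagged, long_set)``.
    Cutoff and assignment radius default to one grid-cell diagonal.
    """
    grid = build_grid(emb, grid_shape)
    pool = trace_trajectories(grid, emb.coords, dt=dt, n_steps=n_steps,
                              n_repeats=n_repeats, sway_sd=sway_sd, seed=seed)
    cutoff = grid.diagonal if similarity_cutoff is None else similarity_cutoff
    long_set = select_long_trajectories(pool, cutoff, n_path=n_path)
    raw_time, cluster, flagged = assign_pseudotime(emb.coords, long_set, pool,
                                                   radius=grid.diagonal)
    shifts = _overlap_shifts(emb.coords, raw_time, cluster, k=overlap_k)
    pseudotime, _ = adjust_time_zones(raw_time, cluster, shifts)
    return pseudotime, cluster, raw_time, flagged, long_set
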