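"""Neighbor graphs and first-moment smoothing.

The relay loss compares each cell's predicted displacement with the
displacements toward its nearest neighbors, so the neighbor set defines
which "observed future states" a cell can be relayed through.  Three
flavors are supported:

* gene-specific: k nearest neighbors in the gene's own (u, s) phase plane,
  after min-max scaling of each axis;
* gene-shared: k nearest neighbors in a feature space shared by all genes —
  the spliced matrix, the concatenated spliced+unspliced matrix, or a
  precomputed low-dimensional embedding;
* first-moment smoothing: each cell's value replaced by the mean over
  itself and its neighbors, the standard kNN denoising of raw counts.

Distances are Euclidean; ties are broken by cell index so graphs are
fully deterministic.  The search is exact (brute force).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeighborGraph", "knn_phase", "knn_shared", "smooth_first_moment"]

MODES = ("phase_gene", "shared_spliced", "shared_spliced_unspliced", "embedding")


@dataclass(frozen=True)
class NeighborGraph:
    """k nearest neighbors per cell, self excluded.

    ``indices`` has shape (n_cells, k); row j lists cell j's neighbors in
    order of increasing distance (ties by cell index).
    """

    indices: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.ndim != 2:
            raise ValueError("indices must be a cells x k matrix")
        n = idx.shape[0]
        if idx.size and ((idx < 0).any() or (idx >= n).any()):
            raise ValueError("neighbor indices out of range")
        if idx.size and (idx == np.arange(n)[:, None]).any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def _exact_knn(X: np.ndarray, k: int, mode: str) -> NeighborGraph:
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    # brute-force squared distances; stable argsort gives index tie-breaking
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return NeighborGraph(indices=order[:, :k], mode=mode)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi - lo <= 0:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def knn_phase(u, s, k: int) -> NeighborGraph:
    """Gene-specific kNN in the min-max-scaled (u, s) phase plane."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape or u.ndim != 1:
        raise ValueError("u and s must be 1-d vectors of equal length")
    X = np.column_stack([_minmax(u), _minmax(s)])
    return _exact_knn(X, k, "phase_gene")


def knn_shared(matrix, k: int, mode: str = "shared_spliced") -> NeighborGraph:
    """Gene-shared kNN on a cells x features matrix.

    ``matrix`` may be the spliced matrix, the horizontally stacked
    spliced+unspliced matrix, or a 2-D embedding; ``mode`` records which.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("matrix must be cells x features with >= 1 feature")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    return _exact_knn(X, k, mode)


def smooth_first_moment(matrix, graph: NeighborGraph) -> np.ndarray:
    """First-moment smoothing: mean over {self} and the k neighbors.

    Reduces technical noise in raw counts before training; with a k=0
    graph this is the identity.
    """
    X = np.asarray(matrix, dtype=float)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[:, None]
    if X.shape[0] != graph.n_cells:
        raise ValueError("graph was built on a different number of cells")
    if graph.k == 0:
        out = X.copy()
    else:
        out = (X + X[graph.indices].sum(axis=1)) / (graph.k + 1)
    return out[:, 0] if one_dim else out
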