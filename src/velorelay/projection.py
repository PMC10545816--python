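"""Projection of high-dimensional velocities onto a 2-D embedding.

Each cell's per-gene velocity vector is compared against the expression
displacement toward each neighbor: the more the displacement
``delta_jj' = s_j' - s_j`` (across genes) correlates with the velocity
``v_j``, the likelier a transition to that neighbor.  An exponential
kernel over the Pearson correlation (width ``sigma = 0.05``) gives a
row-stochastic transition matrix restricted to each cell's neighbor set,
and the projected arrow is the expected unit displacement in embedding
coordinates under that matrix, centered by the uniform distribution:

    v~_j = sum_{j' in N} (P_jj' - 1/|N|) theta^_jj'

where ``theta^`` is the unit vector from cell j to j' in the embedding.
Under a uniform P (no directional information) the arrow vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .neighbors import NeighborGraph

__all__ = ["TransitionMatrix", "EmbeddingVelocity", "transition_matrix", "project_velocity"]


@dataclass
class TransitionMatrix:
    """Sparse cells x cells transition probabilities over neighbor sets."""

    probs: sparse.csr_matrix
    sigma: float
    graph: NeighborGraph

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class EmbeddingVelocity:
    """2-D embedding coordinates and the projected velocity arrows."""

    coords: np.ndarray
    vel2d: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.vel2d = np.asarray(self.vel2d, dtype=float)
        if self.coords.shape != self.vel2d.shape or self.coords.shape[1] != 2:
            raise ValueError("coords and vel2d must both be cells x 2")
        if not (np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.vel2d))):
            raise ValueError("entries must be finite")


def _pearson_rows(v: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Pearson correlation of one vector against each row; constants give 0."""
    vc = v - v.mean()
    vs = np.linalg.norm(vc)
    dc = deltas - deltas.mean(axis=1, keepdims=True)
    ds = np.linalg.norm(dc, axis=1)
    denom = vs * ds
    num = dc @ vc
    return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)


def transition_matrix(velocity, expression, graph: NeighborGraph,
                      sigma: float = 0.05) -> TransitionMatrix:
    """Correlation-kernel transition probabilities over neighbor sets.

    ``velocity`` is the cells x genes matrix of per-gene (spliced)
    velocities; ``expression`` the cells x genes spliced abundances whose
    pairwise differences define the displacements.  Rows normalize to 1
    over each cell's neighbors; a cell with an all-zero velocity gets a
    uniform row (no directional information).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    V = np.asarray(velocity, dtype=float)
    S = np.asarray(expression, dtype=float)
    if V.shape != S.shape:
        raise ValueError("velocity and expression must share a shape")
    n, k = graph.indices.shape
    if V.shape[0] != n:
        raise ValueError("graph built on a different number of cells")

    rows = np.repeat(np.arange(n), k)
    cols = graph.indices.ravel()
    data = np.empty(n * k)
    for j in range(n):
        nbrs = graph.indices[j]
        deltas = S[nbrs] - S[j]
        if np.allclose(V[j], 0.0):
            p = np.full(k, 1.0 / k)
        else:
            corr = _pearson_rows(V[j], deltas)
            w = np.exp(corr / sigma)
            p = w / w.sum()
        data[j * k:(j + 1) * k] = p
    P = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return TransitionMatrix(probs=P, sigma=sigma, graph=graph)


def project_velocity(P: TransitionMatrix, coords) -> EmbeddingVelocity:
    """Project transition probabilities to 2-D embedding arrows.

    ``v~_j = sum_{j'} (P_jj' - 1/|N|) theta^_jj'``; coincident cells
    contribute a zero unit vector.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be cells x 2")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    idx = P.graph.indices
    n, k = idx.shape
    disp = coords[idx] - coords[:, None, :]
    norm = np.linalg.norm(disp, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm[..., None] > 0, disp / np.where(norm[..., None] > 0, norm[..., None], 1.0), 0.0)
    probs = np.asarray(P.probs[np.repeat(np.arange(n), k), idx.ravel()]).reshape(n, k)
    weights = probs - 1.0 / k
    vel = np.einsum("ck,ckd->cd", weights, unit)
    return EmbeddingVelocity(coords=coords, vel2d=vel)
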