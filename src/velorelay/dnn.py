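"""Per-gene relay velocity learner.

One small fully connected network per gene maps each cell's max-scaled
``(u, s)`` to cell-specific kinetic rates ``(alpha, beta, gamma)`` in
``[0, 1]`` (two hidden layers of 100 leaky-ReLU units, sigmoid-squashed
outputs).  The network is trained against the relay loss: the predicted
displacement of cell ``j`` over a time step ``dt``,

    v_j = dt * (alpha - beta*u_j,  beta*u_j - gamma*s_j),

is compared with the observed displacements toward each of its neighbors
``j'``, ``v_j' = (u_j' - u_j, s_j' - s_j)``, and the per-cell loss is
``1 - max_j' cos(v_j, v_j')``; the gene loss is the sum over cells.  A
cell whose best-matching neighbor is its own plausible future state
contributes nothing, so chains of cells "relay" local kinetics across the
phase portrait without a global parametric curve.

Optimization is Adam (learning rate 0.001, weight decay 0.004) on a
randomly permuted subset of cells per epoch, with early stopping when the
full-data loss has not decreased for ``patience`` consecutive checkpoints.
The maximum over neighbors is differentiated through the argmax neighbor;
zero-length vectors contribute cosine 0 and a zero gradient.

Because the relay loss scores either time-orientation of a thin band of
cells almost equally, training starts from an orientation-resolving
initialization: the network is first fitted to local data tangents whose
direction is fixed by two snapshot-kinematic statistics (the clockwise
turn of splicing trajectories in the (s, u) plane and the accumulation of
cells at the flow's fixed points; see :func:`orient_tangents`), and the
relay loss then refines magnitudes and cell-specific rates.

Because the inputs are max-scaled per gene, multiplying a gene's raw
``u`` and ``s`` by any positive constant leaves the training problem — and
hence all predicted rates — exactly unchanged.  Only rate *ratios* (and
velocity directions) are identifiable from snapshot data; helpers that
translate the scaled rates back to the raw coordinate system live in
:mod:`velorelay.evaluation`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .neighbors import NeighborGraph, knn_phase, knn_shared

__all__ = [
    "ExpressionPair",
    "CellRates",
    "TrainConfig",
    "TrainResult",
    "RateNet",
    "predict_rates",
    "relay_loss",
    "velocity_from_rates",
    "train_gene",
    "train_genes",
    "rank_genes_by_loss",
    "derive_gene_seed",
    "orient_tangents",
]


@dataclass(frozen=True)
class ExpressionPair:
    """Per-gene unspliced/spliced abundance across cells."""

    u: np.ndarray
    s: np.ndarray
    cell_ids: tuple = ()

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if u.shape != s.shape or u.ndim != 1:
            raise ValueError("u and s must be 1-d and of equal length")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(s))):
            raise ValueError("u and s must be finite")
        if (u < 0).any() or (s < 0).any():
            raise ValueError("u and s must be non-negative")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "s", s)
        if self.cell_ids and len(self.cell_ids) != u.size:
            raise ValueError("cell_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.u.size


@dataclass
class CellRates:
    """Cell-specific (alpha, beta, gamma) in [0, 1] and the gene's final loss."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    loss: float = np.nan

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.alpha.shape == self.beta.shape == self.gamma.shape):
            raise ValueError("rate vectors must share one shape")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults follow the published recipe).

    The orientation fields control the initialization phase that resolves
    the time-reversal ambiguity of snapshot data before the relay loss
    takes over (see :func:`orient_tangents`): ``orientation`` is one of
    ``auto`` or ``none`` (skip the phase entirely).
    """

    hidden_sizes: tuple = (100, 100)
    learning_rate: float = 0.001
    weight_decay: float = 0.004
    patience: int = 3
    check_every_n_epochs: int = 5
    permutation_ratio: float = 0.125
    dt: float = 0.5
    n_neighbors: int = 30
    neighbor_mode: str = "phase_gene"
    max_epochs: int = 200
    early_stopping: bool = True
    leaky_slope: float = 0.01
    pretrain_epochs: int = 60
    orientation: str = "auto"
    orient_k: int = 400
    orient_anchor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.permutation_ratio <= 1.0):
            raise ValueError("permutation_ratio must be in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.check_every_n_epochs < 1:
            raise ValueError("check_every_n_epochs must be >= 1")
        if self.orientation not in ("auto", "none"):
            raise ValueError("orientation must be auto or none")


@dataclass
class TrainResult:
    """Outcome of training one gene's network."""

    rates: CellRates
    loss_history: list
    converged_epoch: int
    predicted_velocity: np.ndarray
    u_scale: float = 1.0
    s_scale: float = 1.0
    gene: str = ""
    failed: bool = False
    message: str = ""


def derive_gene_seed(seed: int, gene_name: str) -> int:
    """Stable per-gene seed: independent of which other genes are trained."""
    return zlib.crc32(f"{seed}:{gene_name}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# the network


class RateNet:
    """Fully connected (2 -> hidden -> hidden -> 3) rate predictor.

    The per-cell map realizes the batched "2n inputs -> 3n outputs" network
    by weight sharing across cells.  Weights are initialized uniformly in
    ``+/- 1/sqrt(fan_in)`` from a seeded generator.
    """

    def __init__(self, hidden_sizes=(100, 100), leaky_slope: float = 0.01, seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = (2, *hidden_sizes, 3)
        self.leaky_slope = float(leaky_slope)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        a = X
        acts = [X]
        pre = []
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            if i < last:
                a = np.where(z > 0, z, self.leaky_slope * z)
            else:
                a = 1.0 / (1.0 + np.exp(-z))
            pre.append(z)
            acts.append(a)
        if cache:
            return a, (acts, pre)
        return a

    def backward(self, cache, d_out):
        """Gradients of a scalar loss w.r.t. all parameters.

        ``d_out`` is dL/d(sigmoid output).  Returns (weight_grads, bias_grads).
        """
        acts, pre = cache
        last = len(self.weights) - 1
        out = acts[-1]
        delta = d_out * out * (1.0 - out)
        w_grads = [None] * len(self.weights)
        b_grads = [None] * len(self.biases)
        for i in range(last, -1, -1):
            w_grads[i] = acts[i].T @ delta
            b_grads[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                slope = np.where(pre[i - 1] > 0, 1.0, self.leaky_slope)
                delta = delta * slope
        return w_grads, b_grads

    def copy_params(self):
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_params(self, params) -> None:
        ws, bs = params
        self.weights = [w.copy() for w in ws]
        self.biases = [b.copy() for b in bs]


class _Adam:
    """Adam with decoupled-from-nothing L2 weight decay added to gradients
    (the same convention as ``torch.optim.Adam(weight_decay=...)``)."""

    def __init__(self, net: RateNet, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        params = net.weights + net.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, net: RateNet, w_grads, b_grads) -> None:
        self.t += 1
        params = net.weights + net.biases
        grads = list(w_grads) + list(b_grads)
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            if self.wd:
                g = g + self.wd * p
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# loss and velocity


def predict_rates(network: RateNet, u, s) -> CellRates:
    """Apply the network cell-wise to scaled (u, s); outputs lie in [0, 1]."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.size and (u.max() > 1.0 + 1e-6 or s.max() > 1.0 + 1e-6):
        import warnings

        warnings.warn("inputs look unscaled (max > 1); expected per-gene max scaling")
    out = network.forward(np.column_stack([u, s]))
    return CellRates(alpha=out[:, 0], beta=out[:, 1], gamma=out[:, 2])


def velocity_from_rates(u, s, rates: CellRates, dt: float):
    """Predicted per-cell displacement over one time step.

    ``(du, ds) = dt * (alpha - beta*u, beta*u - gamma*s)``, evaluated on the
    same scaling the rates were predicted on.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    du = dt * (rates.alpha - rates.beta * u)
    ds = dt * (rates.beta * u - rates.gamma * s)
    return np.stack([du, ds], axis=-1)


def _neighbor_displacements(u, s, graph: NeighborGraph):
    pos = np.column_stack([u, s])
    D = pos[graph.indices] - pos[:, None, :]
    Dn = np.linalg.norm(D, axis=2)
    return D, Dn


def _cosine_to_neighbors(v, D, Dn):
    """cells x k cosine matrix; zero-length vectors contribute cosine 0."""
    vnorm = np.linalg.norm(v, axis=1)
    dot = np.einsum("cd,ckd->ck", v, D)
    denom = vnorm[:, None] * Dn
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
    return cos, vnorm


def relay_loss(u, s, rates: CellRates, graph: NeighborGraph, dt: float):
    """Total and per-cell relay loss.

    ``loss_j = 1 - max_{j'} cos(v_j, v_j')`` with the convention that the
    cosine involving a zero-length vector is 0; total is the sum over cells.
    """
    if graph.k < 1:
        raise ValueError("relay loss needs at least one neighbor per cell")
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    v = velocity_from_rates(u, s, rates, dt)
    D, Dn = _neighbor_displacements(u, s, graph)
    cos, _ = _cosine_to_neighbors(v, D, Dn)
    per_cell = 1.0 - cos.max(axis=1)
    return float(per_cell.sum()), per_cell


# ---------------------------------------------------------------------------
# orientation of the snapshot flow
#
# A snapshot of cells along a kinetic trajectory fixes the *path* of the
# motion but not, locally, its arrow of time: the relay loss scores either
# orientation of a thin band of cells almost equally.  Two properties of
# first-order splicing kinetics break the tie:
#
# * u leads s.  Differentiating the rate equations gives the phase-plane
#   cross product s_dot*u_ddot - u_dot*s_ddot = (gamma-beta)*u_dot*s_dot -
#   beta*u_dot**2, which is negative for essentially all rate combinations:
#   true motion always turns clockwise in the (s, u) plane, because spliced
#   abundance is a low-pass filter of unspliced abundance.
# * flow points toward accumulation.  Relaxation kinetics decelerate into
#   their fixed points, so with cells spread along trajectories the
#   snapshot density is highest where the flow terminates.
#
# Two globally consistent orientation fields are scored against both
# statistics: the induction/repression rule (cells above the steady-state
# diagonal u = gamma/beta * s move up-right, cells below move down-left)
# and the all-decay rule (everything moves down-left), the latter covering
# transcriptionally silent genes for which no steady-state branch exists.
# The winner orients the local data tangents used to *initialize* the
# network; the relay loss then refines magnitudes and cell-specific rates.


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, np.inf)
    return d2


def orient_tangents(u, s, k: int = 400):
    """Oriented local tangents of the phase portrait with confidences.

    ``u`` and ``s`` are the max-scaled coordinates.  For every cell the
    principal direction of its wide neighborhood is the local tangent;
    its sign is fixed by two clockwise statistics, each weighted by its
    own evidence:

    * origin rotation — along true motion ``u*ds - s*du = beta*u**2 +
      (beta-gamma)*u*s - alpha*s`` is non-negative whenever degradation
      does not outpace splicing, so the state turns clockwise about the
      origin of the (s, u) plane;
    * local turning — differentiating the rate equations gives
      ``s_dot*u_ddot - u_dot*s_ddot < 0``: trajectories also turn
      clockwise locally, which covers transcription-boost take-offs where
      the origin-rotation statistic briefly reverses.

    Returns ``(T, w)``: per-cell oriented tangent targets and non-negative
    confidence weights (agreeing votes reinforce, conflicting votes cancel).
    """
    X = np.column_stack([u, s])
    n = X.shape[0]
    kk = min(k, n - 1)
    d2 = _pairwise_sq(X)
    nbr = np.argpartition(d2, kk - 1, axis=1)[:, :kk]
    P = X[nbr] - X[:, None, :]

    # local PCA of the neighbor cloud (analytic 2x2 eigenvectors)
    cuu = np.einsum("nk,nk->n", P[..., 0], P[..., 0])
    cus = np.einsum("nk,nk->n", P[..., 0], P[..., 1])
    css = np.einsum("nk,nk->n", P[..., 1], P[..., 1])
    theta = 0.5 * np.arctan2(2.0 * cus, cuu - css)
    tau = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    nu = np.stack([-tau[:, 1], tau[:, 0]], axis=1)

    # signed curvature of the band from a local quadratic fit
    xi = P[..., 0] * tau[:, None, 0] + P[..., 1] * tau[:, None, 1]
    eta = P[..., 0] * nu[:, None, 0] + P[..., 1] * nu[:, None, 1]
    a_coef = np.einsum("nk,nk->n", eta, xi**2) / np.maximum((xi**4).sum(1), 1e-30)
    kv = a_coef[:, None] * nu
    # clockwise turning in (s, u) axes: cross_z = t_s * k_u - t_u * k_s < 0
    cz = tau[:, 1] * kv[:, 0] - tau[:, 0] * kv[:, 1]
    sig_cw = np.where(cz == 0, 0.0, -np.sign(cz))
    lam_max = 0.5 * ((cuu + css) + np.sqrt((cuu - css) ** 2 + 4 * cus**2))
    w_cw = np.abs(a_coef) * np.sqrt(np.maximum(lam_max, 0.0))

    # clockwise rotation about the origin: u*tau_s - s*tau_u > 0.  |m| is
    # the perpendicular distance from the origin to the local tangent line;
    # within one band width of zero (near-radial bands) the statistic is
    # meaningless, so those votes are silenced.
    m = u * tau[:, 1] - s * tau[:, 0]
    sig_m = np.sign(m)
    lam_min = 0.5 * ((cuu + css) - np.sqrt((cuu - css) ** 2 + 4 * cus**2))
    band_width = np.sqrt(np.maximum(lam_min, 0.0) / kk)
    w_m = np.where(np.abs(m) > 2.0 * band_width, np.abs(m), 0.0)

    # along-tangent first moment of the neighbor cloud: decelerating flows
    # pile cells ahead, so the offset points forward; covers radial decay
    # rays where both clockwise statistics vanish (down-weighted because it
    # misfires at take-offs, where those statistics are strong)
    mu1 = xi.mean(1)
    sig_mu = np.sign(mu1)
    w_mu = np.abs(mu1)
    # large offsets are edge artifacts (one-sided neighborhoods at band
    # termini), not density trends: silence them
    w_mu = np.where(w_mu <= np.quantile(w_mu, 0.8), w_mu, 0.0)

    def _norm(w):
        mw = w.mean()
        return w / mw if mw > 0 else w

    comb = _norm(w_m) * sig_m + _norm(w_cw) * sig_cw + 0.3 * _norm(w_mu) * sig_mu
    sigma = np.where(comb == 0, 1.0, np.sign(comb))
    weight = np.minimum(np.abs(comb), 3.0)
    return sigma[:, None] * tau, weight


def _target_loss_and_grads(net, X, u, s, T, w, dt):
    """Confidence-weighted cosine loss against fixed target directions."""
    R, cache = net.forward(X, cache=True)
    a, b, g = R[:, 0], R[:, 1], R[:, 2]
    v = np.stack([dt * (a - b * u), dt * (b * u - g * s)], axis=1)
    vn = np.linalg.norm(v, axis=1)
    tn = np.linalg.norm(T, axis=1)
    ok = (vn > 0) & (tn > 0)
    denom = np.where(ok, vn * tn, 1.0)
    cos = np.where(ok, np.einsum("ij,ij->i", v, T) / denom, 0.0)
    loss = float((w * (1.0 - cos)).sum())
    dv = -(T / denom[:, None] - v * (cos / np.where(vn > 0, vn**2, 1.0))[:, None])
    dv[~ok] = 0.0
    dv *= w[:, None]
    g1, g2 = dv[:, 0], dv[:, 1]
    dR = np.stack([dt * g1, dt * u * (g2 - g1), -dt * s * g2], axis=1)
    w_grads, b_grads = net.backward(cache, dR)
    return loss, w_grads, b_grads


# ---------------------------------------------------------------------------
# training


def _batch_loss_and_grads(net, X, u, s, D, Dn, dt):
    """Relay loss over a batch plus parameter gradients (argmax neighbor)."""
    R, cache = net.forward(X, cache=True)
    a, b, g = R[:, 0], R[:, 1], R[:, 2]
    v = np.stack([dt * (a - b * u), dt * (b * u - g * s)], axis=1)
    cos, vnorm = _cosine_to_neighbors(v, D, Dn)
    best = cos.argmax(axis=1)
    rows = np.arange(X.shape[0])
    best_cos = cos[rows, best]
    loss = float((1.0 - best_cos).sum())

    Db = D[rows, best]          # chosen neighbor displacement
    Dbn = Dn[rows, best]
    ok = (vnorm > 0) & (Dbn > 0)
    denom = np.where(ok, vnorm * Dbn, 1.0)
    # d(1 - cos)/dv = -(Db/(|v||Db|) - v cos/|v|^2)
    dv = -(Db / denom[:, None] - v * (best_cos / np.where(vnorm > 0, vnorm**2, 1.0))[:, None])
    dv[~ok] = 0.0
    g1, g2 = dv[:, 0], dv[:, 1]
    dR = np.stack([dt * g1, dt * u * (g2 - g1), -dt * s * g2], axis=1)
    w_grads, b_grads = net.backward(cache, dR)
    return loss, w_grads, b_grads


def _full_loss(net, X, u, s, D, Dn, dt) -> float:
    R = net.forward(X)
    rates = CellRates(alpha=R[:, 0], beta=R[:, 1], gamma=R[:, 2])
    v = velocity_from_rates(u, s, rates, dt)
    cos, _ = _cosine_to_neighbors(v, D, Dn)
    return float((1.0 - cos.max(axis=1)).sum())


def _scale(x: np.ndarray) -> float:
    m = float(np.max(x)) if x.size else 0.0
    return m if m > 0 else 1.0


def build_gene_graph(pair: ExpressionPair, config: TrainConfig,
                     shared_features: np.ndarray | None = None) -> NeighborGraph:
    """Neighbor graph per the configured mode."""
    if config.neighbor_mode == "phase_gene":
        return knn_phase(pair.u, pair.s, config.n_neighbors)
    if shared_features is None:
        raise ValueError(f"mode {config.neighbor_mode!r} needs shared features")
    return knn_shared(shared_features, config.n_neighbors, mode=config.neighbor_mode)


def train_gene(pair: ExpressionPair, graph: NeighborGraph, config: TrainConfig,
               gene_name: str = "gene", flip_orientation: bool = False) -> TrainResult:
    """Train one gene's network and return rates/velocities for every cell.

    Each epoch takes one Adam step on a random ``permutation_ratio``
    fraction of cells; the loss over *all* cells is evaluated at each
    checkpoint (every ``check_every_n_epochs`` epochs) and the best
    checkpoint's weights are returned.  Training stops early when the
    checkpoint loss has not decreased for ``patience`` consecutive
    checkpoints (unless ``early_stopping`` is off).  Results depend only on
    the data and ``(config, gene_name)`` — never on worker count.

    ``flip_orientation`` reverses every orientation tangent target: used by
    :func:`train_genes` to re-fit genes whose first fit looks time-reversed.
    """
    n = pair.n_cells
    if graph.n_cells != n:
        raise ValueError("graph and expression pair disagree on cell count")
    u_scale = _scale(pair.u)
    s_scale = _scale(pair.s)
    u = pair.u / u_scale
    s = pair.s / s_scale
    X = np.column_stack([u, s])
    D, Dn = _neighbor_displacements(u, s, graph)

    gene_seed = derive_gene_seed(config.seed, gene_name)
    rng = np.random.default_rng(gene_seed)
    net = RateNet(config.hidden_sizes, config.leaky_slope, seed=gene_seed)
    opt = _Adam(net, config.learning_rate, config.weight_decay)

    m = max(1, int(round(config.permutation_ratio * n)))
    history: list[tuple[int, float]] = []
    best_loss = np.inf
    best_epoch = 0
    best_params = net.copy_params()
    bad = 0
    failed = False
    message = ""

    # phase 1: orientation pretraining against fixed tangent targets; the
    # recorded checkpoint loss is always the relay loss proper
    pre = config.pretrain_epochs if config.orientation != "none" and n > 5 else 0
    if pre:
        T, Tw = orient_tangents(u, s, k=config.orient_k)
        if flip_orientation:
            T = -T
        for epoch in range(1, pre + 1):
            idx = rng.choice(n, size=m, replace=False)
            loss, w_grads, b_grads = _target_loss_and_grads(
                net, X[idx], u[idx], s[idx], T[idx], Tw[idx], config.dt
            )
            if not np.isfinite(loss):
                failed = True
                message = f"non-finite pretraining loss at epoch {epoch}"
                break
            opt.step(net, w_grads, b_grads)
            if epoch % config.check_every_n_epochs == 0:
                history.append((epoch, _full_loss(net, X, u, s, D, Dn, config.dt)))

    # phase 2: relay loss with early stopping on checkpointed full-data loss.
    # The oriented tangents stay in the gradient as a weak anchor so that
    # the refinement cannot drift into the time-reversed basin; checkpoint
    # and reported losses are always the pure relay loss.
    anchor = config.orient_anchor if pre else 0.0
    epoch = pre
    if not failed:
        for epoch in range(pre + 1, pre + config.max_epochs + 1):
            idx = rng.choice(n, size=m, replace=False)
            loss, w_grads, b_grads = _batch_loss_and_grads(
                net, X[idx], u[idx], s[idx], D[idx], Dn[idx], config.dt
            )
            if not np.isfinite(loss):
                failed = True
                message = f"non-finite training loss at epoch {epoch}"
                break
            if anchor:
                _, wa, ba = _target_loss_and_grads(
                    net, X[idx], u[idx], s[idx], T[idx], Tw[idx], config.dt
                )
                w_grads = [wg + anchor * a for wg, a in zip(w_grads, wa)]
                b_grads = [bg + anchor * a for bg, a in zip(b_grads, ba)]
            opt.step(net, w_grads, b_grads)

            if (epoch - pre) % config.check_every_n_epochs == 0 or \
                    epoch == pre + config.max_epochs:
                ck = _full_loss(net, X, u, s, D, Dn, config.dt)
                history.append((epoch, ck))
                if not np.isfinite(ck):
                    failed = True
                    message = f"non-finite checkpoint loss at epoch {epoch}"
                    break
                if ck < best_loss:
                    best_loss = ck
                    best_epoch = epoch
                    best_params = net.copy_params()
                    bad = 0
                else:
                    bad += 1
                    if config.early_stopping and bad >= config.patience:
                        break

    net.set_params(best_params)
    rates = predict_rates(net, u, s)
    if failed or not np.isfinite(best_loss):
        rates = CellRates(
            alpha=np.full(n, np.nan), beta=np.full(n, np.nan),
            gamma=np.full(n, np.nan), loss=np.nan,
        )
        vel = np.full((n, 2), np.nan)
        return TrainResult(rates, history, best_epoch, vel, u_scale, s_scale,
                           gene=gene_name, failed=True, message=message)
    rates.loss = best_loss
    vel = velocity_from_rates(u, s, rates, config.dt)
    return TrainResult(rates, history, best_epoch, vel, u_scale, s_scale,
                       gene=gene_name)


def train_genes(u_matrix, s_matrix, config: TrainConfig, gene_names=None,
                n_jobs: int = 1, shared_features=None) -> dict:
    """Train every gene of a cells x genes pair of matrices.

    Genes are embarrassingly parallel (per-gene seeds derive from the
    global seed and the gene name, so results are independent of
    ``n_jobs``).  After the first pass, genes whose final loss per cell
    exceeds twice the dataset median — the signature of an orientation
    initialization that fought the data — are refit with flipped tangent
    targets and keep whichever fit has the lower relay loss.  Returns
    ``{gene_name: TrainResult}``.
    """
    U = np.asarray(u_matrix, dtype=float)
    S = np.asarray(s_matrix, dtype=float)
    if U.shape != S.shape or U.ndim != 2:
        raise ValueError("u and s matrices must share a cells x genes shape")
    g = U.shape[1]
    if gene_names is None:
        gene_names = [f"gene{j}" for j in range(g)]
    if len(gene_names) != g:
        raise ValueError("gene_names length mismatch")

    shared_graph = None
    if config.neighbor_mode != "phase_gene":
        if shared_features is None:
            if config.neighbor_mode == "shared_spliced":
                shared_features = S
            elif config.neighbor_mode == "shared_spliced_unspliced":
                shared_features = np.hstack([S, U])
            else:
                raise ValueError("embedding mode requires explicit shared_features")
        shared_graph = knn_shared(shared_features, config.n_neighbors,
                                  mode=config.neighbor_mode)

    def _one(j: int, flip: bool = False) -> TrainResult:
        pair = ExpressionPair(u=U[:, j], s=S[:, j])
        graph = shared_graph if shared_graph is not None else knn_phase(
            pair.u, pair.s, config.n_neighbors
        )
        return train_gene(pair, graph, config, gene_name=gene_names[j],
                          flip_orientation=flip)

    if n_jobs == 1:
        results = [_one(j) for j in range(g)]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(_one)(j) for j in range(g))

    # orientation-retry pass: an anomalously high loss marks a gene whose
    # tangent targets likely pointed against the data's flow
    if config.orientation != "none" and g >= 3:
        losses = np.array([r.rates.loss if not r.failed else np.nan
                           for r in results])
        med = np.nanmedian(losses)
        if np.isfinite(med) and med > 0:
            retry = [j for j in range(g)
                     if np.isfinite(losses[j]) and losses[j] > 2.0 * med]
            if retry:
                if n_jobs == 1:
                    flipped = [_one(j, flip=True) for j in retry]
                else:
                    flipped = Parallel(n_jobs=n_jobs)(
                        delayed(_one)(j, True) for j in retry)
                for j, alt in zip(retry, flipped):
                    if not alt.failed and alt.rates.loss < losses[j]:
                        results[j] = alt
    return dict(zip(gene_names, results))


def rank_genes_by_loss(results: dict) -> list:
    """Gene names ordered by ascending final loss; ties lexicographic.

    Low-loss genes fit the kinetic model well (clean mono-kinetic or
    branching portraits); pattern-less genes rank last.  Failed genes sort
    after all finite losses.
    """
    def key(item):
        name, res = item
        loss = res.rates.loss
        return (not np.isfinite(loss), loss if np.isfinite(loss) else 0.0, name)

    return [name for name, _ in sorted(results.items(), key=key)]
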