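"""Relay velocity learner: loss oracle, gradients, training contracts."""

import numpy as np
import pytest

from velorelay import (
    CellRates,
    ExpressionPair,
    RateNet,
    TrainConfig,
    knn_phase,
    predict_rates,
    rank_genes_by_loss,
    relay_loss,
    train_gene,
    velocity_from_rates,
    extrapolate_state,
)
from velorelay.dnn import (
    _Adam,
    _batch_loss_and_grads,
    _full_loss,
    _neighbor_displacements,
    derive_gene_seed,
)


# ---------------------------------------------------------------------------
# relay loss


def brute_force_relay_loss(u, s, rates, indices, dt):
    """Independent elementwise evaluation of the relay loss."""
    total = 0.0
    per_cell = []
    for j in range(len(u)):
        du = dt * (rates.alpha[j] - rates.beta[j] * u[j])
        ds = dt * (rates.beta[j] * u[j] - rates.gamma[j] * s[j])
        best = -np.inf
        for jp in indices[j]:
            dx, dy = u[jp] - u[j], s[jp] - s[j]
            na = np.hypot(du, ds)
            nb = np.hypot(dx, dy)
            cos = 0.0 if na == 0 or nb == 0 else (du * dx + ds * dy) / (na * nb)
            best = max(best, cos)
        per_cell.append(1.0 - best)
        total += 1.0 - best
    return total, np.array(per_cell)


def test_relay_loss_matches_bruteforce(rng):
    u = rng.random(10)
    s = rng.random(10)
    g = knn_phase(u, s, 3)
    rates = CellRates(alpha=rng.random(10), beta=rng.random(10), gamma=rng.random(10))
    total, per_cell = relay_loss(u, s, rates, g, dt=0.5)
    ref_total, ref_cells = brute_force_relay_loss(u, s, rates, g.indices, 0.5)
    assert total == pytest.approx(ref_total)
    assert np.allclose(per_cell, ref_cells)


def test_relay_loss_parallel_and_antiparallel():
    # two cells on a line; rates chosen so cell 0 points exactly at cell 1
    u = np.array([0.0, 0.5, 1.0])
    s = np.array([0.0, 0.0, 0.0])
    g = knn_phase(u, s, 1)
    # alpha=1, beta=0, gamma=0 -> v = (dt, 0): straight +u for every cell
    rates = CellRates(alpha=np.ones(3), beta=np.zeros(3), gamma=np.zeros(3))
    _, per_cell = relay_loss(u, s, rates, g, dt=0.5)
    assert per_cell[0] == pytest.approx(0.0)   # neighbor ahead: cos=1
    assert per_cell[2] == pytest.approx(2.0)   # only neighbor behind: cos=-1


def test_relay_loss_zero_vector_convention():
    u = np.array([0.5, 0.5])
    s = np.array([0.5, 0.5])
    g = knn_phase(u, s, 1)
    # steady state: predicted displacement is exactly zero -> cosine 0
    rates = CellRates(alpha=np.full(2, 0.5), beta=np.full(2, 1.0), gamma=np.full(2, 1.0))
    total, per_cell = relay_loss(u, s, rates, g, dt=0.5)
    assert np.allclose(per_cell, 1.0)
    assert np.isfinite(total)


def test_loss_bounds(trained_mono_gene):
    res = trained_mono_gene["result"]
    n = trained_mono_gene["pair"].n_cells
    assert 0.0 <= res.rates.loss <= 2.0 * n
    r = res.rates
    for vec in (r.alpha, r.beta, r.gamma):
        assert np.all((vec >= 0.0) & (vec <= 1.0))


# ---------------------------------------------------------------------------
# network and gradients


def test_predict_rates_sigmoid_range_and_determinism(rng):
    net = RateNet(seed=3)
    u = rng.random(20)
    s = rng.random(20)
    r1 = predict_rates(net, u, s)
    r2 = predict_rates(net, u, s)
    for vec in (r1.alpha, r1.beta, r1.gamma):
        assert np.all((vec > 0) & (vec < 1))
    assert np.array_equal(r1.alpha, r2.alpha)
    # identical cells get identical rates
    ru = predict_rates(net, np.full(4, 0.3), np.full(4, 0.6))
    assert np.unique(ru.alpha).size == 1


def test_predict_rates_warns_on_unscaled_input():
    net = RateNet(seed=0)
    with pytest.warns(UserWarning):
        predict_rates(net, np.array([5.0]), np.array([0.1]))


def test_backprop_matches_finite_differences(rng):
    u = rng.uniform(0, 1, 12)
    s = rng.uniform(0, 1, 12)
    g = knn_phase(u, s, 3)
    D, Dn = _neighbor_displacements(u, s, g)
    X = np.column_stack([u, s])
    net = RateNet((8, 8), seed=1)
    _, w_grads, b_grads = _batch_loss_and_grads(net, X, u, s, D, Dn, 0.5)
    eps = 1e-6
    params = net.weights + net.biases
    grads = list(w_grads) + list(b_grads)
    for P, G in zip(params, grads):
        flat = P.reshape(-1)
        for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old = flat[k]
            flat[k] = old + eps
            up = _full_loss(net, X, u, s, D, Dn, 0.5)
            flat[k] = old - eps
            dn = _full_loss(net, X, u, s, D, Dn, 0.5)
            flat[k] = old
            assert (up - dn) / (2 * eps) == pytest.approx(G.reshape(-1)[k], abs=1e-6)


def test_velocity_from_rates_consistency(rng):
    u = rng.random(15)
    s = rng.random(15)
    rates = CellRates(alpha=rng.random(15), beta=rng.random(15), gamma=rng.random(15))
    v = velocity_from_rates(u, s, rates, dt=0.5)
    for j in (0, 7, 14):
        un, sn = extrapolate_state(u[j], s[j], rates.alpha[j], rates.beta[j],
                                   rates.gamma[j], 0.5)
        assert v[j, 0] == pytest.approx(un - u[j])
        assert v[j, 1] == pytest.approx(sn - s[j])
    assert np.allclose(velocity_from_rates(u, s, rates, dt=1.0), 2 * v)


# ---------------------------------------------------------------------------
# training contracts


def test_training_deterministic(trained_mono_gene):
    d = trained_mono_gene
    again = train_gene(d["pair"], d["graph"], d["config"], gene_name="gene0")
    assert np.array_equal(again.rates.alpha, d["result"].rates.alpha)
    assert again.rates.loss == d["result"].rates.loss
    assert again.loss_history == d["result"].loss_history


def test_best_checkpoint_is_history_minimum(trained_mono_gene):
    res = trained_mono_gene["result"]
    losses = [l for _, l in res.loss_history]
    assert res.rates.loss == pytest.approx(min(losses))


def test_scale_invariance_exact(trained_mono_gene):
    """Multiplying raw u and s by a positive constant changes nothing.

    A power-of-two factor keeps the division exact in floating point, so
    the invariance holds bit-for-bit.
    """
    d = trained_mono_gene
    pair = d["pair"]
    scaled = ExpressionPair(u=32.0 * pair.u, s=32.0 * pair.s)
    graph = knn_phase(scaled.u, scaled.s, 30)
    res = train_gene(scaled, graph, d["config"], gene_name="gene0")
    assert np.array_equal(res.rates.alpha, d["result"].rates.alpha)
    assert np.array_equal(res.rates.beta, d["result"].rates.beta)
    assert res.u_scale == pytest.approx(32.0 * d["result"].u_scale)


def test_two_step_alpha_separates(trained_mono_gene):
    """Predicted transcription rate forms an active and a near-zero cluster."""
    d = trained_mono_gene
    ds = d["dataset"]
    alpha = d["result"].rates.alpha
    ind = ds.stage_label == 0
    assert alpha[ind].mean() > 3 * max(alpha[~ind].mean(), 1e-6)
    assert alpha[~ind].mean() < 0.15


def test_gene_seed_stability():
    assert derive_gene_seed(1, "Ntrk2") == derive_gene_seed(1, "Ntrk2")
    assert derive_gene_seed(1, "Ntrk2") != derive_gene_seed(2, "Ntrk2")
    assert derive_gene_seed(1, "Ntrk2") < 2**31


def test_rank_genes_by_loss_orders_and_breaks_ties():
    def res_with(loss):
        r = CellRates(alpha=np.zeros(1), beta=np.zeros(1), gamma=np.zeros(1))
        r.loss = loss
        from velorelay import TrainResult

        return TrainResult(rates=r, loss_history=[], converged_epoch=0,
                           predicted_velocity=np.zeros((1, 2)))

    results = {"b": res_with(0.5), "a": res_with(0.1), "c": res_with(0.5)}
    assert rank_genes_by_loss(results) == ["a", "b", "c"]


def test_adam_step_moves_toward_lower_loss(rng):
    u = rng.uniform(0, 1, 40)
    s = rng.uniform(0, 1, 40)
    g = knn_phase(u, s, 5)
    D, Dn = _neighbor_displacements(u, s, g)
    X = np.column_stack([u, s])
    net = RateNet(seed=5)
    opt = _Adam(net, lr=0.01, weight_decay=0.0)
    before = _full_loss(net, X, u, s, D, Dn, 0.5)
    for _ in range(50):
        _, wg, bg = _batch_loss_and_grads(net, X, u, s, D, Dn, 0.5)
        opt.step(net, wg, bg)
    after = _full_loss(net, X, u, s, D, Dn, 0.5)
    assert after < before
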