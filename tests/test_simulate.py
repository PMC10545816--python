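"""Simulator: regime rate draws, trajectories, noise, downsampling, dropout."""

import numpy as np
import pytest

from velorelay import (
    RegimeSpec,
    apply_dropout,
    closed_form_constant_rates,
    dropout_rate_grid,
    dropout_ratio,
    generate_dataset,
    instantaneous_velocity,
    simulate_dropout_gene,
    simulate_gene,
)


def test_unknown_regime_rejected():
    with pytest.raises(ValueError):
        RegimeSpec("oscillatory")


def test_boost_draw_bounds():
    spec = RegimeSpec("transcriptional_boost", n_cells=400, n_genes=1, seed=1)
    sim = simulate_gene(spec, 0)
    pre = sim["stage"] == 0
    assert np.all((sim["alpha"][pre] >= 1.6) & (sim["alpha"][pre] <= 2.4))
    assert np.all((sim["alpha"][~pre] >= 4.0) & (sim["alpha"][~pre] <= 6.0))
    assert np.all((sim["beta"] >= 1.8) & (sim["beta"] <= 2.2))
    assert np.all((sim["gamma"] >= 0.9) & (sim["gamma"] <= 1.1))


def test_backward_alpha_is_zero_everywhere():
    spec = RegimeSpec("multi_backward", n_cells=300, n_genes=2, seed=3)
    ds = generate_dataset(spec)
    assert np.all(ds.true_alpha == 0.0)


def test_multi_forward_lineage_rate_ranges():
    spec = RegimeSpec("multi_forward", n_cells=500, n_genes=1, seed=2)
    sim = simulate_gene(spec, 0)
    l1 = sim["lineage"] == 0
    assert np.all((sim["alpha"][l1] >= 0.8) & (sim["alpha"][l1] <= 1.2))
    assert np.all((sim["gamma"][l1] >= 0.2) & (sim["gamma"][l1] <= 0.3))
    assert np.all((sim["alpha"][~l1] >= 4.0) & (sim["alpha"][~l1] <= 6.0))
    assert np.all((sim["gamma"][~l1] >= 4.0) & (sim["gamma"][~l1] <= 6.0))


def test_mono_alpha_two_step(mono_dataset):
    """Per gene, true alpha takes exactly the active value and zero."""
    for j in range(mono_dataset.n_genes):
        vals = np.unique(mono_dataset.true_alpha[:, j])
        assert vals.size == 2
        assert vals[0] == 0.0
        assert 1.6 <= vals[1] <= 2.4


def test_noiseless_two_stage_matches_piecewise_closed_form():
    """Mono-kinetic positions agree with the analytic solution chained
    across the induction -> repression switch."""
    spec = RegimeSpec("mono_kinetic", n_cells=250, n_genes=1, noise_sd=0.0, seed=5)
    sim = simulate_gene(spec, 0)
    switch = sim["time"][sim["stage"] == 1].min()  # upper bound on the switch
    a_on = sim["alpha"].max()
    b, g = sim["beta"][0], sim["gamma"][0]
    t_sw = 2.0  # midpoint of the mono/boost span (stage span)
    u_sw, s_sw = closed_form_constant_rates(0.0, 0.0, a_on, b, g, t_sw)
    for i in range(0, 250, 13):
        t = sim["time"][i]
        if sim["stage"][i] == 0:
            u_ref, s_ref = closed_form_constant_rates(0.0, 0.0, a_on, b, g, t)
        else:
            u_ref, s_ref = closed_form_constant_rates(u_sw, s_sw, 0.0, b, g, t - t_sw)
        assert np.isclose(sim["u"][i], u_ref, atol=1e-5)
        assert np.isclose(sim["s"][i], s_ref, atol=1e-5)


def test_noiseless_induction_matches_closed_form_from_origin():
    spec = RegimeSpec("multi_forward", n_cells=300, n_genes=1, noise_sd=0.0, seed=4)
    sim = simulate_gene(spec, 0)
    u_ref, s_ref = np.empty(300), np.empty(300)
    for i in range(300):
        u_ref[i], s_ref[i] = closed_form_constant_rates(
            0.0, 0.0, sim["alpha"][i], sim["beta"][i], sim["gamma"][i], sim["time"][i]
        )
    assert np.allclose(sim["u"], u_ref, atol=1e-5)
    assert np.allclose(sim["s"], s_ref, atol=1e-5)


def test_true_velocity_consistent_with_rate_equations(mono_dataset):
    ds = mono_dataset
    j = 1
    du, dsv = instantaneous_velocity(
        ds.u_true[:, j], ds.s_true[:, j],
        ds.true_alpha[:, j], ds.true_beta[:, j], ds.true_gamma[:, j],
    )
    assert np.allclose(ds.true_velocity[:, j, 0], du)
    assert np.allclose(ds.true_velocity[:, j, 1], dsv)


def test_observed_values_non_negative(mono_dataset):
    assert np.all(mono_dataset.u >= 0)
    assert np.all(mono_dataset.s >= 0)


def test_seeded_determinism():
    spec = RegimeSpec("transcriptional_boost", n_cells=150, n_genes=2, seed=9)
    a = generate_dataset(spec)
    b = generate_dataset(spec)
    assert np.array_equal(a.u, b.u) and np.array_equal(a.s, b.s)
    assert np.array_equal(a.true_alpha, b.true_alpha)


def test_lineage_downsampling_ratio():
    spec = RegimeSpec("transcriptional_boost", n_cells=4000, n_genes=1,
                      lineage_sampling_ratio=0.4, seed=11)
    ds = generate_dataset(spec)
    post = (ds.stage_label == 1).sum()
    pre = (ds.stage_label == 0).sum()
    # binomial thinning of the post-boost stage: post/pre ~ 0.4
    assert 0.3 < post / pre < 0.5


def test_dropout_zero_mean_degenerate():
    U, S = apply_dropout(np.zeros(5), np.zeros(5), n_neighbors=50, seed=0)
    assert (U == 0).all() and (S == 0).all()
    assert dropout_ratio(U, S) == 1.0


def test_dropout_rejects_negative_means():
    with pytest.raises(ValueError):
        apply_dropout(np.array([-0.1]), np.array([1.0]))


def test_poisson_zero_fraction_matches_closed_form(rng):
    lam = 0.8
    U, S = apply_dropout(np.full(200, lam), np.full(200, lam),
                         n_neighbors=200, seed=7)
    expected = np.exp(-lam)
    assert dropout_ratio(U, S) == pytest.approx(expected, abs=0.01)


@pytest.mark.parametrize("target", [50.0, 60.0, 70.0])
def test_dropout_grid_hits_band(target):
    """Selected triples have expected zero fractions inside the band, and
    Poisson draws realize that expectation."""
    triples = dropout_rate_grid(target)
    assert triples, "grid search found no admissible rate triples"
    a, b, g = triples[len(triples) // 2]
    # analytic expectation along the trajectory for this triple
    from velorelay.simulate import _dropout_trajectory, _span

    times = np.linspace(0.0, _span(b, g), 400)
    u, s = _dropout_trajectory(a, b, g, times)
    expected = 100.0 * 0.5 * (np.exp(-u).mean() + np.exp(-s).mean())
    assert abs(expected - target) <= 3.0
    sim = simulate_dropout_gene(a, b, g, n_cells=400, n_neighbors=200, seed=3)
    achieved = dropout_ratio(sim["u_counts"], sim["s_counts"]) * 100
    assert abs(achieved - expected) <= 2.5
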