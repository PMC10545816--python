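"""Standard simulation-benchmark protocols.

Bundles the steps that every simulated evaluation shares: generate a
kinetic regime, denoise the counts by first-moment smoothing over
gene-shared neighbors, train the per-gene networks, and score the results
against the ground truth (rate-ratio recovery, 0.7-cutoff error rates,
convergence epochs, dropout robustness).  These helpers are what the
acceptance script and the heavier tests call.
"""

from __future__ import annotations

import numpy as np

from .dnn import TrainConfig, train_genes
from .evaluation import (
    convergence_epoch,
    pearson_r,
    phase_pooled_ratios,
    predicted_ratio,
    recovery_r2,
    regime_error_rates,
)
from .neighbors import knn_shared, smooth_first_moment
from .simulate import (
    RegimeSpec,
    dropout_rate_grid,
    generate_dataset,
    simulate_dropout_gene,
)

__all__ = [
    "smooth_dataset",
    "run_regime_benchmark",
    "mono_kinetic_recovery",
    "dropout_recovery",
]

SMOOTH_NEIGHBORS = 100  # first-moment smoothing span, gene-shared space


def smooth_dataset(ds, n_neighbors: int = SMOOTH_NEIGHBORS):
    """First-moment smoothing of u and s over gene-shared kNN."""
    feats = np.hstack([ds.s, ds.u])
    graph = knn_shared(feats, min(n_neighbors, ds.n_cells - 1),
                       mode="shared_spliced_unspliced")
    return smooth_first_moment(ds.u, graph), smooth_first_moment(ds.s, graph)


def run_regime_benchmark(regime: str, n_genes: int, n_cells: int = 2000,
                         seed: int = 0, config: TrainConfig | None = None,
                         n_jobs: int = 1, lineage_sampling_ratio: float = 1.0):
    """Simulate a regime, train every gene, return results and metrics.

    Returns ``(dataset, results, report)`` where ``report`` carries the
    per-gene error rates (cosine cutoff 0.7) and convergence epochs.
    """
    spec = RegimeSpec(regime=regime, n_cells=n_cells, n_genes=n_genes,
                      lineage_sampling_ratio=lineage_sampling_ratio, seed=seed)
    ds = generate_dataset(spec)
    su, ss = smooth_dataset(ds)
    config = config or TrainConfig(seed=seed)
    results = train_genes(su, ss, config, gene_names=ds.gene_names, n_jobs=n_jobs)
    errors = regime_error_rates(results, ds)
    epochs = {g: convergence_epoch(r.loss_history)
              for g, r in results.items() if not r.failed and r.loss_history}
    report = {
        "error_rates": errors,
        "median_error_rate": float(np.median(list(errors.values()))) if errors else float("nan"),
        "convergence_epochs": epochs,
        "median_convergence_epoch": float(np.median(list(epochs.values()))) if epochs else float("nan"),
    }
    return ds, results, report


def mono_kinetic_recovery(n_genes: int = 100, n_cells: int = 2000, seed: int = 0,
                          config: TrainConfig | None = None, n_jobs: int = 1):
    """Two-step-alpha recovery benchmark: R^2 of alpha/beta and gamma/beta.

    Pools per-gene, per-phase mean predicted ratios against the truth
    (each phase of a mono-kinetic gene shares one true ratio).
    """
    spec = RegimeSpec(regime="mono_kinetic", n_cells=n_cells, n_genes=n_genes,
                      seed=seed)
    ds = generate_dataset(spec)
    su, ss = smooth_dataset(ds)
    config = config or TrainConfig(seed=seed)
    results = train_genes(su, ss, config, gene_names=ds.gene_names, n_jobs=n_jobs)
    out = {}
    # alpha/beta varies between phases (two-step program): pool per phase.
    pred, true = phase_pooled_ratios(results, ds, "alpha_over_beta")
    out["alpha_over_beta"] = recovery_r2(pred, true)
    # gamma/beta is shared by both phases: one median per gene.
    pred, true = [], []
    for j, name in enumerate(ds.gene_names):
        res = results[name]
        if res.failed:
            continue
        pred.append(float(np.median(predicted_ratio(res, "gamma_over_beta"))))
        true.append(ds.true_gamma[0, j] / ds.true_beta[0, j])
    out["gamma_over_beta"] = recovery_r2(np.array(pred), np.array(true))
    return ds, results, out


def dropout_recovery(levels=(50.0, 60.0, 70.0), n_genes_per_level: int = 25,
                     n_cells: int = 2000, n_neighbors: int = 200, seed: int = 0,
                     config: TrainConfig | None = None, n_jobs: int = 1):
    """Poisson-dropout robustness: Pearson r of alpha/beta and alpha/gamma.

    For each dropout band, rate triples are grid-searched over
    ``[0.1, 1.0]`` (step 0.1); genes observed through Poisson counts of
    200 pseudo-neighbors are smoothed by the neighbor mean and trained.
    The per-level Pearson correlations pool per-gene mean predicted ratios
    against the true draws; the report also carries the minimum over
    levels as the headline summary.
    """
    config = config or TrainConfig(seed=seed)
    report: dict = {"levels": {}}
    for level in levels:
        triples = dropout_rate_grid(level)
        if not triples:
            raise RuntimeError(f"no rate triples hit the {level}% dropout band")
        # stratify picks across the alpha/gamma ratio range: many admissible
        # triples share one ratio, and a small random draw can collapse the
        # truth variance the recovery correlation needs
        ratios = np.array([a / g for a, _, g in triples])
        order = np.argsort(ratios, kind="stable")
        picks = order[np.linspace(0, len(order) - 1, n_genes_per_level).round().astype(int)]
        u_cols, s_cols, names, truths = [], [], [], []
        achieved = []
        for gi, ti in enumerate(picks):
            a, b, g = triples[ti]
            sim = simulate_dropout_gene(a, b, g, n_cells=n_cells,
                                        n_neighbors=n_neighbors,
                                        seed=seed * 100003 + gi)
            u_cols.append(sim["u_smooth"])
            s_cols.append(sim["s_smooth"])
            names.append(f"do{int(level)}_{gi}")
            truths.append((a, b, g))
            achieved.append(
                ((sim["u_counts"] == 0).sum() + (sim["s_counts"] == 0).sum())
                / (sim["u_counts"].size + sim["s_counts"].size)
            )
        U = np.column_stack(u_cols)
        S = np.column_stack(s_cols)
        results = train_genes(U, S, config, gene_names=names, n_jobs=n_jobs)
        pred_ab, true_ab, pred_ag, true_ag = [], [], [], []
        for name, (a, b, g) in zip(names, truths):
            res = results[name]
            if res.failed:
                continue
            pred_ab.append(float(np.median(predicted_ratio(res, "alpha_over_beta"))))
            true_ab.append(a / b)
            pred_ag.append(float(np.median(predicted_ratio(res, "alpha_over_gamma"))))
            true_ag.append(a / g)
        report["levels"][level] = {
            "r_alpha_over_beta": pearson_r(pred_ab, true_ab),
            "r_alpha_over_gamma": pearson_r(pred_ag, true_ag),
            "achieved_dropout_pct": 100.0 * float(np.mean(achieved)),
        }
    report["min_r_alpha_over_beta"] = min(
        v["r_alpha_over_beta"] for v in report["levels"].values())
    report["min_r_alpha_over_gamma"] = min(
        v["r_alpha_over_gamma"] for v in report["levels"].values())
    return report
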