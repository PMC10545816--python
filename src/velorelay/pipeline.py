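"""End-to-end orchestration: train -> project -> pseudotime (-> evaluate).

Glues the library stages into one reproducible run that writes each
stage's CSV plus a provenance JSON.  Every output table is stamped with
the config hash; re-running with the same input, config and seed yields
byte-identical files, and per-gene results are independent of the worker
count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dnn import train_genes
from .io import DatasetContainer, RunConfig, write_stage_csv
from .neighbors import knn_shared
from .projection import transition_matrix, project_velocity
from .pseudotime import estimate_pseudotime

logger = logging.getLogger("velorelay")

__all__ = ["run_pipeline", "results_to_frame", "velocity_matrices", "default_embedding"]


def results_to_frame(results: dict, container: DatasetContainer) -> pd.DataFrame:
    """Tidy per-cell, per-gene table of rates, velocities and losses."""
    frames = []
    for j, gene in enumerate(container.gene_names):
        res = results[gene]
        frames.append(pd.DataFrame({
            "cell": container.cell_ids,
            "gene": gene,
            "u": container.unspliced[:, j],
            "s": container.spliced[:, j],
            "alpha": res.rates.alpha,
            "beta": res.rates.beta,
            "gamma": res.rates.gamma,
            "du": res.predicted_velocity[:, 0],
            "ds": res.predicted_velocity[:, 1],
            "loss": res.rates.loss,
        }))
    return pd.concat(frames, ignore_index=True)


def velocity_matrices(results: dict, container: DatasetContainer):
    """Scaled spliced-velocity and spliced-expression matrices (cells x genes).

    Both are on each gene's max-scaled axis so that the correlation in the
    transition kernel weighs genes comparably.
    """
    n, g = container.n_cells, container.n_genes
    vel = np.zeros((n, g))
    expr = np.zeros((n, g))
    for j, gene in enumerate(container.gene_names):
        res = results[gene]
        if res.failed:
            continue
        vel[:, j] = res.predicted_velocity[:, 1]
        expr[:, j] = container.spliced[:, j] / res.s_scale
    return vel, expr


def default_embedding(container: DatasetContainer) -> np.ndarray:
    """The container's embedding, or a PCA(2) of spliced counts as fallback."""
    if container.embedding is not None:
        return np.asarray(container.embedding, dtype=float)
    from sklearn.decomposition import PCA

    logger.info("no embedding provided; falling back to PCA of spliced counts")
    return PCA(n_components=2, random_state=0).fit_transform(container.spliced)


def run_pipeline(config: RunConfig, container: DatasetContainer, out_dir) -> dict:
    """Run every stage in order, writing stage CSVs and provenance.

    Returns a dict with the in-memory stage results (``results``,
    ``velocity_table``, ``embedding``, ``projected``, ``pseudotime_table``).
    Any stage failure aborts with the stage name in the error message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    def _stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def _smooth():
        if config.smooth_n <= 0 or container.n_cells <= config.smooth_n:
            return container.unspliced, container.spliced
        feats = np.hstack([container.spliced, container.unspliced])
        graph = knn_shared(feats, config.smooth_n, mode="shared_spliced_unspliced")
        from .neighbors import smooth_first_moment

        return (smooth_first_moment(container.unspliced, graph),
                smooth_first_moment(container.spliced, graph))

    u_in, s_in = _stage("smooth", _smooth)

    results = _stage("velocity", lambda: train_genes(
        u_in, s_in, config.train_config(),
        gene_names=container.gene_names, n_jobs=config.jobs,
    ))
    table = results_to_frame(results, container)
    write_stage_csv(table, out / "velocity.csv", chash)

    coords = _stage("embedding", lambda: default_embedding(container))

    def _project():
        vel, expr = velocity_matrices(results, container)
        k = min(config.projection_k, container.n_cells - 1)
        graph = knn_shared(expr, k, mode="shared_spliced")
        P = transition_matrix(vel, expr, graph, sigma=config.sigma)
        return project_velocity(P, coords)

    emb = _stage("project", _project)
    proj_df = pd.DataFrame({
        "cell": container.cell_ids,
        "x": emb.coords[:, 0], "y": emb.coords[:, 1],
        "vx": emb.vel2d[:, 0], "vy": emb.vel2d[:, 1],
    })
    write_stage_csv(proj_df, out / "projected.csv", chash)

    def _pt():
        return estimate_pseudotime(
            emb, grid_shape=config.grid_shape, n_steps=config.n_steps,
            n_repeats=config.n_repeats, n_path=config.n_path, seed=config.seed,
        )

    pseudotime, cluster, raw_time, flagged, _ = _stage("pseudotime", _pt)
    pt_df = pd.DataFrame({
        "cell": container.cell_ids,
        "cluster": cluster,
        "raw_time": raw_time,
        "pseudotime": pseudotime,
        "flagged": flagged.astype(int),
    })
    write_stage_csv(pt_df, out / "pseudotime.csv", chash)

    provenance = {
        "tool": "velorelay",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "n_cells": container.n_cells,
        "n_genes": container.n_genes,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))

    return {
        "results": results,
        "velocity_table": table,
        "embedding": coords,
        "projected": emb,
        "pseudotime_table": pt_df,
        "config_hash": chash,
    }
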