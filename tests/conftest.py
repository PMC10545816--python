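"""Shared fixtures: small simulated datasets and one trained gene.

Session-scoped so the expensive pieces (ODE integration, network training)
run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from velorelay import (
    ExpressionPair,
    RegimeSpec,
    TrainConfig,
    generate_dataset,
    knn_phase,
    train_gene,
)
from velorelay.benchmark import smooth_dataset


@pytest.fixture(scope="session")
def mono_dataset():
    """Noisy two-step-transcription dataset, 600 cells x 4 genes."""
    spec = RegimeSpec("mono_kinetic", n_cells=600, n_genes=4, seed=0)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def mono_smoothed(mono_dataset):
    su, ss = smooth_dataset(mono_dataset, n_neighbors=50)
    return su, ss


@pytest.fixture(scope="session")
def trained_mono_gene(mono_dataset, mono_smoothed):
    """One trained gene on the smoothed mono dataset plus its inputs."""
    su, ss = mono_smoothed
    pair = ExpressionPair(u=su[:, 0], s=ss[:, 0])
    graph = knn_phase(pair.u, pair.s, 30)
    config = TrainConfig(seed=0, permutation_ratio=0.25)
    result = train_gene(pair, graph, config, gene_name="gene0")
    return {"pair": pair, "graph": graph, "config": config, "result": result,
            "dataset": mono_dataset, "gene_index": 0}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
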