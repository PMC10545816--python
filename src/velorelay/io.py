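"""Readers and writers for layered expression containers and stage tables.

The canonical in-memory object is :class:`DatasetContainer`: cells-as-rows
unspliced and spliced matrices plus cell/gene identifiers, an optional 2-D
embedding and optional cell labels.  Supported on-disk dialects:

* ``csv_pair`` — two CSV files (``unspliced.csv`` / ``spliced.csv``) with a
  cell-id index column and gene-name header;
* ``loom`` — an HDF5 file following the loom convention (genes as rows;
  transposed on read) with ``spliced``/``unspliced`` layers, read directly
  with h5py;
* ``h5ad`` — an AnnData file whose ``layers`` carry ``spliced``/``unspliced``
  (the smoothed ``Ms``/``Mu`` aliases are accepted).

Readers never reorder cells: the identifier order in the file is the
contract across all downstream stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dnn import TrainConfig

logger = logging.getLogger("velorelay")

__all__ = ["DatasetContainer", "RunConfig", "read_container", "write_container"]

_LAYER_ALIASES = {"spliced": ("spliced", "Ms"), "unspliced": ("unspliced", "Mu")}


@dataclass
class DatasetContainer:
    """Cells x genes unspliced/spliced matrices with metadata."""

    unspliced: np.ndarray
    spliced: np.ndarray
    cell_ids: list
    gene_names: list
    embedding: np.ndarray | None = None
    cell_labels: list | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unspliced = np.asarray(self.unspliced, dtype=float)
        self.spliced = np.asarray(self.spliced, dtype=float)
        if self.unspliced.shape != self.spliced.shape:
            raise ValueError(
                f"layer shapes disagree: unspliced {self.unspliced.shape} "
                f"vs spliced {self.spliced.shape}"
            )
        n, g = self.unspliced.shape
        if len(self.cell_ids) != n or len(self.gene_names) != g:
            raise ValueError("identifier lengths do not match the matrices")
        if len(set(self.cell_ids)) != n or len(set(self.gene_names)) != g:
            raise ValueError("cell and gene identifiers must be unique")

    @property
    def n_cells(self) -> int:
        return self.unspliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.unspliced.shape[1]


@dataclass(frozen=True)
class RunConfig:
    """Every knob of a full run, serializable to a flat dict."""

    # preprocessing: first-moment smoothing span (0 disables)
    smooth_n: int = 100
    # training
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
    # projection
    sigma: float = 0.05
    projection_k: int = 200
    # pseudotime
    grid_shape: tuple = (30, 30)
    n_steps: int = 500
    n_repeats: int = 10
    n_path: int | None = None
    # run
    jobs: int = 1
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in d:
            d = {**d, "grid_shape": tuple(d["grid_shape"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            patience=self.patience,
            check_every_n_epochs=self.check_every_n_epochs,
            permutation_ratio=self.permutation_ratio,
            dt=self.dt,
            n_neighbors=self.n_neighbors,
            neighbor_mode=self.neighbor_mode,
            max_epochs=self.max_epochs,
            early_stopping=self.early_stopping,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# readers


def _infer_dialect(path: str) -> str:
    p = str(path)
    if "," in p or p.endswith(".csv") or Path(p).is_dir():
        return "csv_pair"
    if p.endswith(".loom"):
        return "loom"
    if p.endswith(".h5ad"):
        return "h5ad"
    raise ValueError(f"cannot infer dialect from {path!r}; pass dialect explicitly")


def _read_csv_pair(path: str) -> DatasetContainer:
    if "," in str(path):
        u_path, s_path = (Path(p.strip()) for p in str(path).split(",", 1))
    else:
        base = Path(path)
        u_path, s_path = base / "unspliced.csv", base / "spliced.csv"
    for p in (u_path, s_path):
        if not p.exists():
            raise FileNotFoundError(p)
    u = pd.read_csv(u_path, index_col=0, comment="#")
    s = pd.read_csv(s_path, index_col=0, comment="#")
    if list(u.columns) != list(s.columns) or list(u.index) != list(s.index):
        raise ValueError(
            "csv_pair mismatch: unspliced and spliced tables must share "
            "identical cell index and gene columns"
        )
    return DatasetContainer(
        unspliced=u.to_numpy(), spliced=s.to_numpy(),
        cell_ids=[str(i) for i in u.index], gene_names=[str(c) for c in u.columns],
    )


def _pick_layer(available: dict, canonical: str):
    for alias in _LAYER_ALIASES[canonical]:
        if alias in available:
            return available[alias]
    raise KeyError(
        f"missing layer {canonical!r} (accepted aliases "
        f"{_LAYER_ALIASES[canonical]}); available: {sorted(available)}"
    )


def _read_loom(path: str) -> DatasetContainer:
    with h5py.File(path, "r") as f:
        layers = {name: f["layers"][name][:] for name in f["layers"]}
        u = _pick_layer(layers, "unspliced")
        s = _pick_layer(layers, "spliced")
        # loom stores genes as rows, cells as columns
        logger.info("loom dialect: transposing genes-as-rows matrices")
        u, s = u.T, s.T
        row_attrs = f.get("row_attrs", {})
        col_attrs = f.get("col_attrs", {})

        def _names(attrs, keys, n, prefix):
            for key in keys:
                if key in attrs:
                    vals = attrs[key][:]
                    return [v.decode() if isinstance(v, bytes) else str(v) for v in vals]
            return [f"{prefix}{i}" for i in range(n)]

        gene_names = _names(row_attrs, ("Gene", "var_names"), u.shape[1], "gene")
        cell_ids = _names(col_attrs, ("CellID", "obs_names"), u.shape[0], "cell")
    return DatasetContainer(unspliced=u, spliced=s, cell_ids=cell_ids,
                            gene_names=gene_names)


def _read_h5ad(path: str) -> DatasetContainer:
    import anndata as ad

    adata = ad.read_h5ad(path)
    layers = {k: np.asarray(adata.layers[k]) for k in adata.layers.keys()}
    u = _pick_layer(layers, "unspliced")
    s = _pick_layer(layers, "spliced")
    embedding = None
    for key in ("X_umap", "X_tsne", "X_pca"):
        if key in adata.obsm:
            embedding = np.asarray(adata.obsm[key])[:, :2]
            break
    labels = None
    for key in ("clusters", "celltype", "cell_type"):
        if key in adata.obs:
            labels = [str(v) for v in adata.obs[key]]
            break
    return DatasetContainer(
        unspliced=u, spliced=s,
        cell_ids=[str(i) for i in adata.obs_names],
        gene_names=[str(v) for v in adata.var_names],
        embedding=embedding, cell_labels=labels,
    )


def read_container(path, dialect: str | None = None) -> DatasetContainer:
    """Read a layered dataset; cells-as-rows orientation is normalized."""
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv_pair":
        return _read_csv_pair(path)
    if dialect == "loom":
        return _read_loom(path)
    if dialect == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_container(container: DatasetContainer, out_dir,
                    config_hash: str = "") -> None:
    """Write a container as a csv_pair (plus embedding/labels if present)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat in (("unspliced", container.unspliced), ("spliced", container.spliced)):
        df = pd.DataFrame(mat, index=container.cell_ids, columns=container.gene_names)
        write_stage_csv(df, out / f"{name}.csv", config_hash, index=True)
    if container.embedding is not None:
        emb = pd.DataFrame(container.embedding, index=container.cell_ids,
                           columns=["x", "y"])
        write_stage_csv(emb, out / "embedding.csv", config_hash, index=True)
    if container.cell_labels is not None:
        lab = pd.DataFrame({"label": container.cell_labels}, index=container.cell_ids)
        write_stage_csv(lab, out / "labels.csv", config_hash, index=True)


def write_stage_csv(df: pd.DataFrame, path, config_hash: str = "",
                    index: bool = False) -> None:
    """CSV writer that stamps the config hash as a leading comment line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# velorelay config_hash={config_hash}\n")
        df.to_csv(fh, index=index)
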