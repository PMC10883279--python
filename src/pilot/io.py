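"""Readers and writers for the formats the pipeline touches.

Cell tables come as delimited text (columns ``cell_id, sample, cluster,
<features...>``), MatrixMarket triplets with ``cells.tsv`` / ``features.tsv``
sidecars, or AnnData ``.h5ad`` with named obs columns.  Distance matrices and
result tables round-trip through TSV; every CLI run writes a JSON manifest
with parameters, seed and package version.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from pilot.dataset import CellDataset
from pilot.ot_core import SampleDistanceMatrix

log = logging.getLogger("pilot")


def read_dataset(
    path: str | Path,
    format: str | None = None,
    sample_col: str = "sample",
    cluster_col: str = "cluster",
    embedding_key: str = "X_pca",
) -> CellDataset:
    """Load a clustered cell table from CSV/TSV, MTX sidecars, or .h5ad.

    ``format`` is inferred from the suffix when omitted (``.csv``, ``.tsv``,
    ``.mtx``, ``.h5ad``).  Cells with missing sample or cluster labels are
    dropped (count logged).
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".h5ad": "h5ad"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format in ("csv", "tsv"):
        return _read_table(path, "," if format == "csv" else "\t", sample_col, cluster_col)
    if format == "mtx":
        return _read_mtx(path, sample_col, cluster_col)
    if format == "h5ad":
        return _read_h5ad(path, sample_col, cluster_col, embedding_key)
    raise ValueError(f"unknown format {format!r}")


def _drop_unlabeled(df: pd.DataFrame, sample_col: str, cluster_col: str) -> pd.DataFrame:
    bad = df[sample_col].isna() | df[cluster_col].isna()
    if bad.any():
        log.warning("dropping %d cells with missing sample/cluster labels", int(bad.sum()))
    return df[~bad]


def _read_table(path: Path, sep: str, sample_col: str, cluster_col: str) -> CellDataset:
    df = pd.read_csv(path, sep=sep)
    for col in (sample_col, cluster_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found; available: {list(df.columns)}")
    df = _drop_unlabeled(df, sample_col, cluster_col)
    feature_cols = [c for c in df.columns if c not in ("cell_id", sample_col, cluster_col)]
    return CellDataset(
        features=df[feature_cols].to_numpy(dtype=float),
        sample_of_cell=df[sample_col].to_numpy(),
        cluster_of_cell=df[cluster_col].to_numpy(),
        feature_names=feature_cols,
    )


def _read_mtx(path: Path, sample_col: str, cluster_col: str) -> CellDataset:
    """MatrixMarket cells x features matrix with cells.tsv / features.tsv sidecars."""
    matrix = sio.mmread(path).tocsr()
    cells = pd.read_csv(path.parent / "cells.tsv", sep="\t")
    features = pd.read_csv(path.parent / "features.tsv", sep="\t")
    for col in (sample_col, cluster_col):
        if col not in cells.columns:
            raise ValueError(f"column {col!r} not found in cells.tsv; available: {list(cells.columns)}")
    cells = _drop_unlabeled(cells, sample_col, cluster_col)
    matrix = matrix[cells.index.to_numpy()]
    return CellDataset(
        features=matrix,
        sample_of_cell=cells[sample_col].to_numpy(),
        cluster_of_cell=cells[cluster_col].to_numpy(),
        feature_names=features.iloc[:, 0].astype(str).tolist(),
    )


def _read_h5ad(path: Path, sample_col: str, cluster_col: str, embedding_key: str) -> CellDataset:
    import anndata as ad

    adata = ad.read_h5ad(path)
    for col in (sample_col, cluster_col):
        if col not in adata.obs.columns:
            raise ValueError(
                f"obs column {col!r} not found; available: {list(adata.obs.columns)}"
            )
    obs = adata.obs
    keep = (~obs[sample_col].isna() & ~obs[cluster_col].isna()).to_numpy()
    if not keep.all():
        log.warning("dropping %d cells with missing sample/cluster labels", int((~keep).sum()))
    emb = None
    if embedding_key in adata.obsm:
        emb = np.asarray(adata.obsm[embedding_key])[keep]
    x = adata.X[keep]
    return CellDataset(
        features=x.copy() if sparse.issparse(x) else np.asarray(x),
        sample_of_cell=obs[sample_col].to_numpy()[keep],
        cluster_of_cell=obs[cluster_col].to_numpy()[keep],
        embedding=emb,
        feature_names=[str(v) for v in adata.var_names],
    )


def write_dataset(dataset: CellDataset, path: str | Path, format: str = "tsv") -> Path:
    """Write a dataset as a delimited cell table (dense) for round-tripping."""
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
    df = pd.DataFrame(dataset.dense_features(), columns=names)
    df.insert(0, "cluster", dataset.cluster_of_cell)
    df.insert(0, "sample", dataset.sample_of_cell)
    df.insert(0, "cell_id", [f"cell{i}" for i in range(dataset.n_cells)])
    df.to_csv(path, sep=sep, index=False)
    return path


def write_dataset_mtx(dataset: CellDataset, out_dir: str | Path) -> Path:
    """Write matrix.mtx plus cells.tsv / features.tsv sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = dataset.features
    if not sparse.issparse(mat):
        mat = sparse.csr_matrix(np.asarray(mat, dtype=float))
    sio.mmwrite(out / "matrix.mtx", mat)
    pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(dataset.n_cells)],
            "sample": dataset.sample_of_cell,
            "cluster": dataset.cluster_of_cell,
        }
    ).to_csv(out / "cells.tsv", sep="\t", index=False)
    names = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
    pd.DataFrame({"feature": names}).to_csv(out / "features.tsv", sep="\t", index=False)
    return out / "matrix.mtx"


def write_dataset_h5ad(dataset: CellDataset, path: str | Path) -> Path:
    import anndata as ad

    names = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
    adata = ad.AnnData(
        X=dataset.features if sparse.issparse(dataset.features) else np.asarray(dataset.features, float),
        obs=pd.DataFrame(
            {"sample": dataset.sample_of_cell, "cluster": dataset.cluster_of_cell},
            index=[f"cell{i}" for i in range(dataset.n_cells)],
        ),
        var=pd.DataFrame(index=names),
    )
    if dataset.embedding is not None:
        adata.obsm["X_pca"] = dataset.embedding
    adata.write_h5ad(Path(path))
    return Path(path)


def write_distance_matrix(matrix: SampleDistanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.as_frame().to_csv(path, sep="\t", index_label="sample", float_format="%.12g")
    return path


def read_distance_matrix(path: str | Path) -> SampleDistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # absorb write/read rounding
    np.fill_diagonal(values, 0.0)
    return SampleDistanceMatrix(values=values, sample_ids=[str(s) for s in df.index])


def write_manifest(path: str | Path, parameters: dict) -> Path:
    """JSON run manifest: parameters, seed and package version."""
    from pilot import __version__

    path = Path(path)
    payload = {"pilot_version": __version__, "parameters": parameters}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path


def setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
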