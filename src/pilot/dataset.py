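"""Container for an integrated, clustered multi-sample cell/structure matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class CellDataset:
    """Integrated cell x feature matrix with per-cell sample and cluster labels.

    Cells may be single cells described by gene expression or tissue
    structures described by morphometric features; both are treated
    identically.  Sample and cluster names are kept in a fixed lexicographic
    order so that every downstream matrix (counts, proportions, costs,
    distances) is indexed consistently.

    Parameters
    ----------
    features
        ``(n_cells, n_features)`` dense or sparse matrix of expression or
        morphometric values.
    sample_of_cell
        Length ``n_cells`` array of sample identifiers.
    cluster_of_cell
        Length ``n_cells`` array of cluster labels.
    embedding
        Optional ``(n_cells, n_components)`` low-dimensional coordinates
        (e.g. principal components) used to position cluster centroids for
        the transport cost.  If absent, :meth:`ensure_embedding` computes
        principal components of the standardized features.
    feature_names, sample_metadata
        Optional feature names and a per-sample covariate table indexed by
        sample id.
    """

    features: np.ndarray | sparse.spmatrix
    sample_of_cell: np.ndarray
    cluster_of_cell: np.ndarray
    embedding: np.ndarray | None = None
    feature_names: list[str] | None = None
    sample_metadata: pd.DataFrame | None = None
    sample_ids: list[str] = field(init=False)
    cluster_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.sample_of_cell = np.asarray(self.sample_of_cell).astype(str)
        self.cluster_of_cell = np.asarray(self.cluster_of_cell).astype(str)
        n = self.features.shape[0]
        if self.sample_of_cell.shape[0] != n or self.cluster_of_cell.shape[0] != n:
            raise ValueError(
                "sample_of_cell and cluster_of_cell must have one entry per cell "
                f"(features has {n} rows)"
            )
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if self.embedding.shape[0] != n:
                raise ValueError("embedding must have the same number of rows as features")
        # fixed lexicographic ordering of ids; all matrices are indexed by it
        self.sample_ids = sorted(np.unique(self.sample_of_cell).tolist())
        self.cluster_names = sorted(np.unique(self.cluster_of_cell).tolist())
        if len(self.sample_ids) < 2:
            raise ValueError("at least two samples are required")
        if len(self.cluster_names) < 2:
            raise ValueError("at least two cell clusters are required")
        if self.feature_names is not None and len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length does not match number of features")
        if self.sample_metadata is not None:
            missing = set(self.sample_ids) - set(self.sample_metadata.index.astype(str))
            if missing:
                raise ValueError(f"sample_metadata is missing samples: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_names)

    def counts(self) -> pd.DataFrame:
        """Sample x cluster table of cell counts ``z_lk``."""
        ct = pd.crosstab(
            pd.Series(self.sample_of_cell, name="sample"),
            pd.Series(self.cluster_of_cell, name="cluster"),
        )
        return ct.reindex(index=self.sample_ids, columns=self.cluster_names, fill_value=0)

    def ensure_embedding(self, n_components: int = 30) -> np.ndarray:
        """Return the stored embedding, computing PCA of standardized features if absent.

        Keeps ``min(n_components, n_features - 1, n_cells - 1)`` components.
        """
        if self.embedding is not None:
            return self.embedding
        from sklearn.decomposition import PCA

        x = self.features.toarray() if sparse.issparse(self.features) else np.asarray(self.features, float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
        k = min(n_components, x.shape[1] - 1, x.shape[0] - 1)
        if k < 1:
            raise ValueError("too few features/cells to compute an embedding")
        self.embedding = PCA(n_components=k, svd_solver="full").fit_transform(x)
        return self.embedding

    def dense_features(self) -> np.ndarray:
        if sparse.issparse(self.features):
            return self.features.toarray()
        return np.asarray(self.features, dtype=float)
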