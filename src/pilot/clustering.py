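"""Graph-based clustering of samples from the Wasserstein distance matrix."""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from sklearn.metrics import silhouette_score

from pilot.ot_core import SampleDistanceMatrix


@dataclass
class SampleClustering:
    """Leiden community assignment of samples with its silhouette quality."""

    labels: np.ndarray  # 1..G
    resolution: float
    silhouette: float
    knn: int
    sample_ids: list[str]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def _knn_graph(distances: SampleDistanceMatrix, knn: int) -> ig.Graph:
    """Symmetric kNN graph with bounded edge weights 1 / (1 + d)."""
    d = distances.values
    n = d.shape[0]
    if knn >= n:
        raise ValueError(f"knn ({knn}) must be smaller than the number of samples ({n})")
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        neighbors = [j for j in order if j != i][:knn]
        for j in neighbors:
            edges.add((min(i, j), max(i, j)))
    edge_list = sorted(edges)
    weights = [1.0 / (1.0 + d[i, j]) for i, j in edge_list]
    g = ig.Graph(n=n, edges=edge_list)
    g.es["weight"] = weights
    return g


def _silhouette(distances: SampleDistanceMatrix, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        return float("-inf")
    return float(silhouette_score(distances.values, labels, metric="precomputed"))


def cluster_samples(
    distances: SampleDistanceMatrix,
    resolution: float = 1.0,
    knn: int | None = None,
    seed: int = 0,
) -> SampleClustering:
    """Leiden clustering of the sample kNN graph at a fixed resolution.

    Deterministic for a fixed seed.  Default ``knn = max(5, floor(sqrt(L)))``.
    """
    n = distances.n_samples
    if knn is None:
        knn = max(5, int(np.sqrt(n)))
    g = _knn_graph(distances, knn)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership, dtype=int) + 1
    sil = _silhouette(distances, labels)
    return SampleClustering(
        labels=labels,
        resolution=float(resolution),
        silhouette=sil,
        knn=knn,
        sample_ids=list(distances.sample_ids),
    )


def select_resolution(
    distances: SampleDistanceMatrix,
    grid: list[float] | None = None,
    knn: int | None = None,
    seed: int = 0,
) -> SampleClustering:
    """Pick the Leiden resolution maximizing the silhouette over a grid.

    Ties favour the smallest resolution.  Raises if no grid point produces
    more than one cluster (silhouette undefined everywhere).
    """
    if grid is None:
        grid = [round(0.1 * i, 2) for i in range(1, 11)]
    if len(grid) == 0:
        raise ValueError("resolution grid is empty")
    best: SampleClustering | None = None
    for r in sorted(grid):
        c = cluster_samples(distances, resolution=r, knn=knn, seed=seed)
        if best is None or c.silhouette > best.silhouette:
            best = c
    assert best is not None
    if not np.isfinite(best.silhouette):
        raise ValueError(
            "every resolution in the grid produced a single cluster; widen the grid"
        )
    return best
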