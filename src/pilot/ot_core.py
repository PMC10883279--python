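"""Optimal-transport core: sample cluster distributions, cluster costs and
pairwise Wasserstein distances.

Each sample ``l`` is summarized as a probability vector ``p_l`` over the ``K``
shared cell clusters.  Proportions are estimated as the posterior mode of a
Dirichlet-multinomial model whose prior adds pseudo cell counts proportional
to the global cluster distribution, which stabilizes rare clusters in
low-coverage samples.  The cost of moving mass between clusters ``i`` and
``j`` is the cosine distance between the coordinate-wise medians of their
cells in a low-dimensional embedding.  The Wasserstein distance between two
samples is the optimal value of the transportation linear program

    min_T  sum_ij t_ij c_ij    s.t.  t_ij >= 0,
                                     sum_j t_ij = p_source[i],
                                     sum_i t_ij = p_target[j],

solved exactly (dual simplex), never by an entropic approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import pdist, squareform

from pilot.dataset import CellDataset

_SUPPORTED_METRICS = ("cosine", "euclidean", "manhattan", "chebyshev")
_DIST_TOL = 1e-8


@dataclass
class ProportionModel:
    """MAP cluster-proportion estimates for each sample.

    ``proportions[l, k]`` is the posterior-mode probability of observing
    cluster ``k`` in sample ``l`` under a ``Dir(alpha)`` prior with
    ``alpha_k = (N_k / N) * c`` (pseudo counts weighted by the global cluster
    distribution, total prior mass ``c``).
    """

    counts: np.ndarray
    prior_weights: np.ndarray
    prior_strength: float
    proportions: np.ndarray
    sample_ids: list[str]
    cluster_names: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.cluster_names)


@dataclass
class ClusterCostMatrix:
    """Cluster medians and the symmetric cluster-to-cluster cost matrix."""

    medians: np.ndarray
    costs: np.ndarray
    metric_name: str
    cluster_names: list[str]


@dataclass
class TransportResult:
    """Optimal transport plan and its total cost (the Wasserstein distance)."""

    plan: np.ndarray
    distance: float


@dataclass
class SampleDistanceMatrix:
    """Symmetric sample x sample distance matrix with ids."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def estimate_proportions(dataset: CellDataset, prior_strength: float = 0.1) -> ProportionModel:
    """Estimate per-sample cluster proportions with a Dirichlet-multinomial MAP.

    With ``z_lk`` the cell count of cluster ``k`` in sample ``l``, ``N_l`` the
    sample's cell total and ``alpha_k = (N_k / N) * prior_strength``, the
    estimate is ``(z_lk + alpha_k) / (N_l + sum_i alpha_i)``.  At
    ``prior_strength = 0`` this reduces to the empirical proportion; for very
    large values it shrinks to the global cluster distribution ``N_k / N``.
    """
    if prior_strength < 0:
        raise ValueError("prior_strength must be non-negative")
    counts = dataset.counts().to_numpy(dtype=float)
    n_per_sample = counts.sum(axis=1)
    for sid, nl in zip(dataset.sample_ids, n_per_sample):
        if nl == 0:
            raise ValueError(f"sample {sid!r} has zero cells")
    global_frac = counts.sum(axis=0) / counts.sum()
    alpha = global_frac * prior_strength
    props = (counts + alpha) / (n_per_sample + alpha.sum())[:, None]
    if prior_strength == 0 and np.any(props == 0):
        warnings.warn(
            "prior_strength=0 with samples missing clusters yields zero proportions",
            stacklevel=2,
        )
    return ProportionModel(
        counts=counts.astype(int),
        prior_weights=alpha,
        prior_strength=float(prior_strength),
        proportions=props,
        sample_ids=list(dataset.sample_ids),
        cluster_names=list(dataset.cluster_names),
    )


def cluster_medians(dataset: CellDataset) -> ClusterCostMatrix:
    """Coordinate-wise median of each cluster's cells in the embedding.

    Medians (rather than means) damp the effect of outlying cells.  Returns a
    :class:`ClusterCostMatrix` with the ``costs`` field left empty; pass the
    medians to :func:`cost_matrix` to fill it.
    """
    emb = dataset.ensure_embedding()
    medians = np.empty((dataset.n_clusters, emb.shape[1]))
    for k, name in enumerate(dataset.cluster_names):
        mask = dataset.cluster_of_cell == name
        if not mask.any():
            raise ValueError(f"cluster {name!r} has no cells")
        medians[k] = np.median(emb[mask], axis=0)
    return ClusterCostMatrix(
        medians=medians,
        costs=np.zeros((dataset.n_clusters, dataset.n_clusters)),
        metric_name="",
        cluster_names=list(dataset.cluster_names),
    )


def cost_matrix(
    medians: np.ndarray | ClusterCostMatrix, metric: str = "cosine"
) -> ClusterCostMatrix:
    """Pairwise dissimilarity between cluster medians.

    The default cosine cost is ``c_ij = 1 - (M_i . M_j) / (|M_i| |M_j|)``,
    bounded in ``[0, 2]``; euclidean, manhattan and chebyshev are available
    as alternatives.
    """
    names: list[str] | None = None
    if isinstance(medians, ClusterCostMatrix):
        names = medians.cluster_names
        medians = medians.medians
    medians = np.asarray(medians, dtype=float)
    if np.isnan(medians).any():
        raise ValueError("cluster medians contain NaN")
    if metric not in _SUPPORTED_METRICS:
        raise ValueError(f"metric must be one of {_SUPPORTED_METRICS}")
    if metric == "cosine":
        norms = np.linalg.norm(medians, axis=1)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(
                f"cluster median {bad} has zero norm; cosine cost undefined "
                "(empty or constant cluster upstream?)"
            )
        costs = squareform(pdist(medians, metric="cosine"))
    else:
        scipy_metric = {"manhattan": "cityblock", "chebyshev": "chebyshev", "euclidean": "euclidean"}[metric]
        costs = squareform(pdist(medians, metric=scipy_metric))
    costs = np.maximum(costs, 0.0)
    costs = (costs + costs.T) / 2.0
    np.fill_diagonal(costs, 0.0)
    if names is None:
        names = [str(i) for i in range(medians.shape[0])]
    return ClusterCostMatrix(medians=medians, costs=costs, metric_name=metric, cluster_names=names)


def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    total = p.sum()
    if abs(total - 1.0) > _DIST_TOL:
        raise ValueError(f"{name} sums to {total:.12g}, not 1 (tolerance {_DIST_TOL})")
    return p / total  # renormalize deviations within tolerance


def solve_transport(
    p_source: np.ndarray, p_target: np.ndarray, costs: np.ndarray
) -> TransportResult:
    """Exact optimal transport between two cluster distributions.

    Solves the transportation LP with the HiGHS dual-simplex solver and
    returns the optimal plan ``T`` (row sums = source, column sums = target)
    and the Wasserstein distance ``sum_ij t_ij c_ij``.
    """
    p_source = _check_distribution(p_source, "p_source")
    p_target = _check_distribution(p_target, "p_target")
    costs = np.asarray(costs, dtype=float)
    k = p_source.shape[0]
    if p_target.shape[0] != k or costs.shape != (k, k):
        raise ValueError("dimension mismatch between distributions and costs")
    if not np.all(np.isfinite(costs)):
        raise ValueError("costs must be finite")

    # marginal constraints: one redundant equality dropped for a full-rank system
    a_eq = np.zeros((2 * k - 1, k * k))
    b_eq = np.empty(2 * k - 1)
    for i in range(k):
        a_eq[i, i * k : (i + 1) * k] = 1.0
        b_eq[i] = p_source[i]
    for j in range(k - 1):
        a_eq[k + j, j::k] = 1.0
        b_eq[k + j] = p_target[j]
    res = linprog(costs.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs-ds")
    if not res.success:  # pragma: no cover - linprog is robust on feasible transport LPs
        raise RuntimeError(f"transport LP failed: {res.message}")
    plan = np.maximum(res.x.reshape(k, k), 0.0)
    distance = float(np.sum(plan * costs))
    return TransportResult(plan=plan, distance=distance)


def pairwise_distances(
    proportions: ProportionModel, costs: ClusterCostMatrix
) -> SampleDistanceMatrix:
    """Wasserstein distance between every pair of samples.

    Only the upper triangle is solved; the matrix is mirrored by symmetry of
    the transport problem.
    """
    if proportions.proportions.shape[1] != costs.costs.shape[0]:
        raise ValueError(
            "number of clusters differs between proportions "
            f"({proportions.proportions.shape[1]}) and costs ({costs.costs.shape[0]})"
        )
    p = proportions.proportions
    n = p.shape[0]
    values = np.zeros((n, n))
    for l in range(n):
        for q in range(l + 1, n):
            d = solve_transport(p[l], p[q], costs.costs).distance
            values[l, q] = values[q, l] = d
    return SampleDistanceMatrix(values=values, sample_ids=list(proportions.sample_ids))


def proportion_baseline_distance(proportions: ProportionModel) -> SampleDistanceMatrix:
    """Baseline sample distance: cosine distance between raw proportion vectors.

    Ignores cluster-to-cluster similarity entirely; used as a benchmark
    reference for the transport distance.
    """
    d = squareform(pdist(proportions.proportions, metric="cosine"))
    d = np.maximum((d + d.T) / 2.0, 0.0)
    np.fill_diagonal(d, 0.0)
    return SampleDistanceMatrix(values=d, sample_ids=list(proportions.sample_ids))
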