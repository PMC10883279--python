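"""Sample-level trajectory inference from a distance matrix.

A diffusion map is built on the sample Wasserstein distance matrix: a
self-tuning Gaussian affinity

    W^s(i, j) = exp(-d(i, j)^2 / (eps * rho_i * rho_j))

with per-sample bandwidth ``rho_i`` equal to the mean distance to the k
nearest neighbours, row-normalized to a transition matrix ``M = D^-1 W^s``,
whose non-trivial leading eigenvectors give low-dimensional coordinates.  A
path backbone is then fitted to the 2-D coordinates (minimum spanning tree,
longest path), every sample is projected onto it, and samples are ranked by
arc length from a root sample — the per-sample disease-progression score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path

from pilot.ot_core import SampleDistanceMatrix


@dataclass
class DiffusionEmbedding:
    """Affinity, transition matrix and spectrum of the sample diffusion map."""

    sample_ids: list[str]
    affinity: np.ndarray
    scale: float
    bandwidths: np.ndarray
    knn: int
    transition: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    coordinates: np.ndarray | None = None


@dataclass
class TrajectoryResult:
    """2-D diffusion coordinates, backbone path and progression ranks."""

    sample_ids: list[str]
    coordinates: np.ndarray
    backbone: np.ndarray  # ordered (n_nodes, 2) polyline through backbone samples
    backbone_samples: list[str]
    root_sample: str
    arc_position: np.ndarray  # arc-length position of each sample's projection
    progression: np.ndarray  # ranks 1..L from the root


def _default_knn(n: int) -> int:
    return max(5, int(np.sqrt(n)))


def affinity_matrix(
    distances: SampleDistanceMatrix,
    scale: float = 1.0,
    knn: int | None = None,
    bandwidths: np.ndarray | None = None,
) -> DiffusionEmbedding:
    """Self-tuning Gaussian affinity of the sample distance matrix.

    The bandwidth ``rho_i`` is the mean distance from sample ``i`` to its
    ``knn`` nearest neighbours (excluding itself), which makes the affinity
    invariant to a global rescaling of the distances.  An explicit
    ``bandwidths`` vector overrides the kNN rule.
    """
    d = distances.values
    n = d.shape[0]
    if knn is None:
        knn = _default_knn(n)
    if knn >= n:
        raise ValueError(f"knn ({knn}) must be smaller than the number of samples ({n})")
    if not np.any(d > 0):
        raise ValueError("all distances are zero; affinity is degenerate")
    if bandwidths is not None:
        rho = np.asarray(bandwidths, dtype=float)
    else:
        sorted_d = np.sort(d, axis=1)  # column 0 is the zero self-distance
        rho = sorted_d[:, 1 : knn + 1].mean(axis=1)
    for i, r in enumerate(rho):
        if r == 0:
            raise ValueError(
                f"bandwidth of sample {distances.sample_ids[i]!r} is zero "
                "(duplicate samples at distance 0)"
            )
    aff = np.exp(-(d**2) / (scale * np.outer(rho, rho)))
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return DiffusionEmbedding(
        sample_ids=list(distances.sample_ids),
        affinity=aff,
        scale=float(scale),
        bandwidths=rho,
        knn=knn,
    )


def transition_and_spectrum(
    embedding: DiffusionEmbedding, n_comp: int = 2
) -> DiffusionEmbedding:
    """Row-normalize the affinity and take its leading non-trivial eigenvectors.

    The transition matrix ``M = D^-1 W^s`` shares its spectrum with the
    symmetric conjugate ``D^-1/2 W^s D^-1/2``, which is decomposed with a
    dense symmetric eigensolver.  The trivial constant eigenvector
    (eigenvalue 1) is dropped; the next ``n_comp`` eigenvectors, each scaled
    by its eigenvalue, are the diffusion coordinates.
    """
    aff = embedding.affinity
    n = aff.shape[0]
    if n_comp > n - 1:
        raise ValueError("n_comp must be at most L - 1")
    deg = aff.sum(axis=1)
    if np.any(deg <= 1e-300):
        raise ValueError("affinity graph is disconnected (numerically zero row)")
    inv_sqrt = 1.0 / np.sqrt(deg)
    sym = aff * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    # eigenvectors of M = D^-1 W^s recovered from the symmetric conjugate
    psi = inv_sqrt[:, None] * evecs[:, order]
    # deterministic sign: largest-magnitude entry positive
    for j in range(psi.shape[1]):
        i = int(np.argmax(np.abs(psi[:, j])))
        if psi[i, j] < 0:
            psi[:, j] = -psi[:, j]
    coords = psi[:, 1 : n_comp + 1] * evals[1 : n_comp + 1]
    embedding.transition = aff / deg[:, None]
    embedding.eigenvalues = evals
    embedding.eigenvectors = psi
    embedding.coordinates = coords
    return embedding


def _tree_longest_path(coords: np.ndarray) -> list[int]:
    """Diameter path of the Euclidean minimum spanning tree of 2-D points."""
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    mst = minimum_spanning_tree(dist).toarray()
    tree = mst + mst.T
    # double sweep: farthest node from an arbitrary node, then farthest from that
    d0 = shortest_path(tree, method="D", indices=0)
    a = int(np.argmax(d0))
    da, pred = shortest_path(tree, method="D", indices=a, return_predecessors=True)
    b = int(np.argmax(da))
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def _project_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Arc-length position of the orthogonal projection of each point."""
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    positions = np.empty(points.shape[0])
    for i, p in enumerate(points):
        best_d, best_s = np.inf, 0.0
        for s in range(seg_vec.shape[0]):
            v = seg_vec[s]
            denom = v @ v
            t = 0.0 if denom == 0 else np.clip((p - poly[s]) @ v / denom, 0.0, 1.0)
            proj = poly[s] + t * v
            dd = np.linalg.norm(p - proj)
            if dd < best_d - 1e-12:
                best_d, best_s = dd, cum[s] + t * seg_len[s]
        positions[i] = best_s
    return positions


def _rank_with_id_ties(values: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """Ranks 1..L; ties broken deterministically by sample-id order."""
    id_order = np.argsort(np.argsort(sample_ids))
    order = np.lexsort((id_order, values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def fit_backbone_and_progression(
    embedding: DiffusionEmbedding,
    root: str = "auto",
    status: "object | None" = None,
    control_label: str | None = None,
) -> TrajectoryResult:
    """Fit a path backbone to the diffusion coordinates and rank samples along it.

    The backbone is the diameter path of the minimum spanning tree of the 2-D
    coordinates; samples are orthogonally projected onto the polyline and
    ranked by arc length from the end nearest the root sample (rank 1 = root
    end).  ``root="auto"`` picks the sample with the smallest first diffusion
    coordinate; if a per-sample ``status`` series and ``control_label`` are
    given, the root is instead the control-labeled sample at the extreme of
    the first coordinate nearest the bulk of the controls.
    """
    if embedding.coordinates is None:
        raise ValueError("run transition_and_spectrum before fitting a backbone")
    coords = embedding.coordinates[:, :2]
    ids = embedding.sample_ids
    n = coords.shape[0]
    if n < 4:
        raise ValueError("backbone requires at least 4 samples")
    if root == "auto":
        if status is not None and control_label is not None:
            import pandas as pd

            st = pd.Series(status)
            st.index = st.index.astype(str)
            ctrl = np.array([st.get(s) == control_label for s in ids])
            if not ctrl.any():
                raise ValueError(f"no sample has status {control_label!r}")
            dc1 = coords[:, 0]
            # anchor the root at whichever end of dc1 the controls cluster on
            if np.median(dc1[ctrl]) <= np.median(dc1):
                root = ids[int(np.flatnonzero(ctrl)[np.argmin(dc1[ctrl])])]
            else:
                root = ids[int(np.flatnonzero(ctrl)[np.argmax(dc1[ctrl])])]
        else:
            root = ids[int(np.argmin(coords[:, 0]))]
    if root not in ids:
        raise ValueError(f"root sample {root!r} not found")
    root_idx = ids.index(root)

    path = _tree_longest_path(coords)
    poly = coords[path]
    pos = _project_to_polyline(coords, poly)
    # orient the path so the root projects near the start
    total = pos.max() if pos.max() > 0 else 1.0
    if pos[root_idx] > total - pos[root_idx]:
        path = path[::-1]
        poly = coords[path]
        pos = _project_to_polyline(coords, poly)
    ranks = _rank_with_id_ties(pos, ids)
    return TrajectoryResult(
        sample_ids=list(ids),
        coordinates=coords,
        backbone=poly,
        backbone_samples=[ids[i] for i in path],
        root_sample=root,
        arc_position=pos,
        progression=ranks,
    )


def combine_progressions(
    progressions: list[np.ndarray], sample_ids: list[str]
) -> np.ndarray:
    """Combine progression scores over the same samples by element-wise sum.

    The summed scores are re-ranked 1..L (ties broken by sample-id order), so
    trajectories measured on different structure types (e.g. glomeruli and
    tubules of the same biopsies) merge into a single ordering.
    """
    if not progressions:
        raise ValueError("no progressions to combine")
    import pandas as pd

    arrs = []
    for p in progressions:
        if isinstance(p, pd.Series):
            if list(p.index.astype(str)) != list(sample_ids):
                raise ValueError("progression sample ids do not match")
            p = p.to_numpy()
        arrs.append(np.asarray(p, dtype=float))
    length = len(sample_ids)
    for a in arrs:
        if a.shape[0] != length:
            raise ValueError("all progressions must cover the same samples")
    total = np.sum(arrs, axis=0)
    return _rank_with_id_ties(total, sample_ids)
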