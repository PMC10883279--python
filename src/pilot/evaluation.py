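"""Benchmark metrics: ARI, silhouette, AUCPR of an ordering, Spearman vs.
ordinal severity, and the Friedman-Nemenyi multi-dataset rank test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, average_precision_score, silhouette_score

from pilot.ot_core import SampleDistanceMatrix


@dataclass
class BenchmarkTable:
    """Per-dataset method ranks with Friedman test and Nemenyi post-hoc p-values."""

    methods: list[str]
    datasets: list[str]
    scores: np.ndarray  # methods x datasets
    ranks: np.ndarray  # methods x datasets (rank 1 = best)
    mean_ranks: np.ndarray
    friedman_statistic: float
    friedman_p: float
    pairwise_p: pd.DataFrame


class AucprResult(NamedTuple):
    value: float
    orientation: int  # +1: higher score = positive class; -1: reversed


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (permutation model)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def silhouette_by_labels(distances: SampleDistanceMatrix, labels) -> float:
    """Mean silhouette of given labels directly on the distance matrix."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 labels")
    return float(silhouette_score(distances.values, labels, metric="precomputed"))


def aucpr_ordering(progression, labels) -> AucprResult:
    """Area under the precision-recall curve of an ordering against binary labels.

    Trajectory direction is arbitrary, so both orientations of the score are
    evaluated and the better one returned with its orientation.  Average
    precision (step-wise interpolation) is used as the integrator.
    """
    score = np.asarray(progression, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    fwd = float(average_precision_score(y, score))
    rev = float(average_precision_score(y, -score))
    return AucprResult(fwd, 1) if fwd >= rev else AucprResult(rev, -1)


def spearman_vs_ordinal(progression, ordinal) -> float:
    """Spearman correlation (midrank ties) of progression vs. ordered severity."""
    score = np.asarray(progression, dtype=float)
    ordv = np.asarray(ordinal, dtype=float)
    if score.size < 3:
        raise ValueError("at least 3 samples are required")
    if np.unique(ordv).size < 2:
        raise ValueError("ordinal variable is constant")
    rho, _ = stats.spearmanr(score, ordv)
    return float(rho)


def friedman_nemenyi(
    scores: np.ndarray | pd.DataFrame, larger_is_better: bool = True
) -> BenchmarkTable:
    """Friedman rank test over datasets with Nemenyi pairwise post-hoc.

    ``scores`` is a methods x datasets matrix of one benchmark metric.  Ranks
    are per dataset (rank 1 = best, average ranks for ties).  The Nemenyi
    p-value for a method pair derives from the studentized range distribution
    of the mean-rank difference.
    """
    if isinstance(scores, pd.DataFrame):
        methods = [str(m) for m in scores.index]
        datasets = [str(d) for d in scores.columns]
        scores = scores.to_numpy(dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
        methods = [f"method_{i}" for i in range(scores.shape[0])]
        datasets = [f"dataset_{j}" for j in range(scores.shape[1])]
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain NaN")
    m, d = scores.shape
    if m < 2 or d < 3:
        raise ValueError("need at least 2 methods and 3 datasets")
    direction = -scores if larger_is_better else scores
    ranks = np.apply_along_axis(stats.rankdata, 0, direction)
    mean_ranks = ranks.mean(axis=1)
    if np.allclose(ranks, ranks[:1, :]):
        fstat, fp = 0.0, 1.0
    else:
        fstat, fp = stats.friedmanchisquare(*[scores[i] for i in range(m)])
    se = np.sqrt(m * (m + 1) / (6.0 * d))
    pw = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, m, np.inf))
            pw[i, j] = pw[j, i] = min(p, 1.0)
    return BenchmarkTable(
        methods=methods,
        datasets=datasets,
        scores=scores,
        ranks=ranks,
        mean_ranks=mean_ranks,
        friedman_statistic=float(fstat),
        friedman_p=float(fp),
        pairwise_p=pd.DataFrame(pw, index=methods, columns=methods),
    )
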