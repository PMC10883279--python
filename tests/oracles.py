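"""Independent reference computations used as test oracles.

These deliberately avoid the code paths of the package: the transport oracle
enumerates basic feasible solutions of the transportation LP instead of
calling an LP solver, and the statistics oracles evaluate textbook formulas
directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_wasserstein(p: np.ndarray, q: np.ndarray, costs: np.ndarray) -> float:
    """Exact transport cost by enumerating vertices of the transportation polytope.

    Every vertex of the feasible set is a basic solution of the (2K-1)
    independent marginal constraints; the optimum of a bounded LP is attained
    at a vertex, so the minimum over all feasible basic solutions is exact.
    Practical for K <= 4.
    """
    k = len(p)
    m = 2 * k - 1
    a = np.zeros((m, k * k))
    b = np.empty(m)
    for i in range(k):
        a[i, i * k : (i + 1) * k] = 1.0
        b[i] = p[i]
    for j in range(k - 1):
        a[k + j, j::k] = 1.0
        b[k + j] = q[j]
    c = np.asarray(costs, float).ravel()
    cols_list = np.array(list(combinations(range(k * k), m)))
    bases = np.stack([a[:, cs] for cs in cols_list])
    sign, _ = np.linalg.slogdet(bases)
    ok = sign != 0
    solutions = np.linalg.solve(bases[ok], b)
    best = np.inf
    for cs, x in zip(cols_list[ok], solutions):
        if np.all(x >= -1e-9):
            best = min(best, float(c[cs] @ x))
    return best


def reference_welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and Satterthwaite dof from the textbook formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(t), float(dof)


def reference_bh(p: np.ndarray) -> np.ndarray:
    """BH step-up by the explicit min-cummax recursion on sorted p-values."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = prev
    return adj


def reference_ari(a: np.ndarray, b: np.ndarray) -> float:
    """ARI from the contingency-table formula, computed from scratch."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(1)).sum()
    sum_b = comb2(table.sum(0)).sum()
    n = comb2(a.size)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    return float((sum_ij - expected) / (max_index - expected))


def reference_friedman(scores: np.ndarray, larger_is_better: bool = True) -> float:
    """Friedman chi-square by the textbook formula (no ties expected)."""
    from scipy.stats import rankdata

    direction = -scores if larger_is_better else scores
    ranks = np.apply_along_axis(rankdata, 0, direction)
    m, d = scores.shape
    rbar = ranks.mean(axis=1)
    return float(12.0 * d / (m * (m + 1)) * np.sum((rbar - (m + 1) / 2.0) ** 2))
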