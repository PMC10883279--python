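"""Statistical interpretation of trajectories and sample clusters.

Trajectory interpretation fits, per feature, three robust polynomial trend
models of the (rank-standardized) progression score p in [0, 1]:

    linear            x = mu + b1 * p
    quadratic         x = mu + b1 * p^2
    linear_quadratic  x = mu + b1 * p + b2 * p^2

under the Huber least-squares criterion (threshold delta, default 1.35, on
MAD-standardized residuals) via iteratively reweighted least squares.  Model
quality uses a modified R^2 whose residual sum of squares is the Huber
penalty, so single outlying cells cannot dominate the fit.  Whether a
cluster's fitted curve differs from the background curve is assessed with a
Wald chi-square test contrasting the two curves at a grid of progression
points, with degrees of freedom from eigenvalue-thresholding of the contrast
covariance.

Cluster-level interpretation compares cell-cluster proportions between sample
groups with Welch's t-test and per-gene expression with an empirical-Bayes
moderated t-test (gene-wise variances shrunk toward a common prior).  All
p-value families are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from pilot.dataset import CellDataset
from pilot.ot_core import ProportionModel

_FAMILIES = ("linear", "quadratic", "linear_quadratic")


@dataclass
class TrendFit:
    feature_id: str
    family: str  # linear | quadratic | linear_quadratic | none
    intercept: float
    coefficients: np.ndarray  # (b1,) or (b1, b2); empty for "none"
    delta: float
    r2_mod: float
    p_value: float
    p_adjusted: float | None = None


@dataclass
class WaldResult:
    feature_id: str
    cluster: str
    statistic: float
    dof: int
    p_value: float
    grid_size: int
    family: str
    p_adjusted: float | None = None


@dataclass
class GroupTestResult:
    feature_id: str
    group_a: str
    group_b: str
    statistic: float
    dof: float
    p_value: float
    effect: float
    test: str
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# Huber trend regression


def _design(p: np.ndarray, family: str) -> np.ndarray:
    if family == "linear":
        return np.column_stack([np.ones_like(p), p])
    if family == "quadratic":
        return np.column_stack([np.ones_like(p), p**2])
    if family == "linear_quadratic":
        return np.column_stack([np.ones_like(p), p, p**2])
    raise ValueError(f"unknown family {family!r}")


def _mad_scale(r: np.ndarray) -> float:
    return float(np.median(np.abs(r - np.median(r))) / 0.6745)


def _huber_irls(
    x: np.ndarray, y: np.ndarray, delta: float, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """IRLS for the Huber criterion with per-iteration MAD residual scaling.

    Returns (beta, weights, scale, covariance) where the covariance is the
    classical estimate from the final weighted-least-squares step.
    """
    n, k = x.shape
    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    w = np.ones(n)
    scale = 1.0
    for _ in range(max_iter):
        r = y - x @ beta
        scale = _mad_scale(r)
        if scale < 1e-12:
            w = np.ones(n)
            break
        u = np.abs(r) / scale
        w = np.where(u <= delta, 1.0, delta / u)
        xw = x * w[:, None]
        beta_new = np.linalg.solve(x.T @ xw, xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    r = y - x @ beta
    dof = max(n - k, 1)
    # M-estimator (sandwich) covariance with Huber's small-sample correction;
    # the naive WLS covariance from the final IRLS step underestimates the
    # sampling variance and makes downstream Wald tests anti-conservative
    delta_abs = delta * scale if scale > 1e-12 else delta
    psi = np.clip(r, -delta_abs, delta_abs)
    psi_prime = (np.abs(r) <= delta_abs).astype(float)
    m1 = float(psi_prime.mean())
    if m1 <= 0:
        m1 = 1.0
    kappa = 1.0 + (k / n) * float(psi_prime.var()) / m1**2
    sigma2 = kappa * float(np.sum(psi**2) / dof) / m1**2
    cov = sigma2 * np.linalg.pinv(x.T @ x)
    return beta, w, scale, cov


def _huber_ss_res(r: np.ndarray, delta_abs: float) -> float:
    """Residual sum with Huber penalization of residuals beyond the threshold."""
    a = np.abs(r)
    quad = a <= delta_abs
    return float(np.sum(r[quad] ** 2) + np.sum(delta_abs * (a[~quad] - delta_abs / 2.0)))


def _fit_family(
    p: np.ndarray, y: np.ndarray, family: str, delta: float
) -> dict:
    x = _design(p, family)
    n, k = x.shape
    beta, w, scale, cov = _huber_irls(x, y, delta)
    r = y - x @ beta
    delta_abs = delta * scale if scale > 1e-12 else delta
    ss_res = _huber_ss_res(r, delta_abs)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_mod = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # overall F-test against intercept-only on Huber-weighted sums of squares
    ybar_w = float(np.sum(w * y) / np.sum(w))
    sst_w = float(np.sum(w * (y - ybar_w) ** 2))
    ssr_w = float(np.sum(w * r**2))
    if sst_w <= ssr_w or ssr_w <= 0:
        p_model = 0.0 if ssr_w < sst_w else 1.0
    else:
        f = ((sst_w - ssr_w) / (k - 1)) / (ssr_w / (n - k))
        p_model = float(stats.f.sf(f, k - 1, n - k))
    # per-coefficient two-sided t-tests from the final WLS covariance
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_coef = 2.0 * stats.t.sf(np.abs(tvals), n - k)
    return {
        "family": family,
        "beta": beta,
        "cov": cov,
        "r2_mod": r2_mod,
        "p_model": p_model,
        "p_coef": p_coef,
        "weights": w,
        "scale": scale,
    }


def standardize_pseudotime(pseudotime: np.ndarray) -> np.ndarray:
    """Map progression scores/ranks to [0, 1] so the Huber threshold is scale-free."""
    p = np.asarray(pseudotime, dtype=float)
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise ValueError("pseudotime is constant")
    return (p - lo) / (hi - lo)


def fit_trend_models(
    values: np.ndarray,
    pseudotime: np.ndarray,
    delta: float = 1.35,
    alpha: float = 0.05,
    feature_id: str = "feature",
) -> TrendFit:
    """Stepwise robust trend fit of a feature against progression.

    All three polynomial families are fitted by Huber IRLS; a family is a
    candidate when its overall F-test and every non-intercept coefficient are
    significant at ``alpha`` (the coefficient requirement keeps the nesting
    linear/quadratic < linear_quadratic from always favouring the largest
    model).  Among candidates the family with the highest modified R^2 is
    reported; with no candidate the family is ``"none"``.
    """
    y = np.asarray(values, dtype=float)
    if y.shape[0] < 10:
        raise ValueError("at least 10 observations are required")
    p = standardize_pseudotime(pseudotime)
    if p.shape[0] != y.shape[0]:
        raise ValueError("values and pseudotime lengths differ")
    if float(np.var(y)) == 0.0:
        return TrendFit(feature_id, "none", float(y[0]), np.array([]), delta, 0.0, 1.0)
    fits = [_fit_family(p, y, fam, delta) for fam in _FAMILIES]
    candidates = [
        f for f in fits if f["p_model"] < alpha and np.all(f["p_coef"][1:] < alpha)
    ]
    if not candidates:
        return TrendFit(feature_id, "none", float(y.mean()), np.array([]), delta, 0.0, 1.0)
    best = max(candidates, key=lambda f: f["r2_mod"])
    return TrendFit(
        feature_id=feature_id,
        family=best["family"],
        intercept=float(best["beta"][0]),
        coefficients=np.asarray(best["beta"][1:], dtype=float),
        delta=delta,
        r2_mod=float(best["r2_mod"]),
        p_value=float(best["p_model"]),
    )


def fit_trend_table(
    values: np.ndarray,
    pseudotime: np.ndarray,
    feature_ids: list[str],
    delta: float = 1.35,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit trends for a matrix of features (columns) and BH-adjust model p-values."""
    fits = [
        fit_trend_models(values[:, j], pseudotime, delta, alpha, feature_ids[j])
        for j in range(values.shape[1])
    ]
    padj = bh_adjust(np.array([f.p_value for f in fits]))
    rows = []
    for f, q in zip(fits, padj):
        f.p_adjusted = float(q)
        b = list(f.coefficients) + [np.nan] * (2 - len(f.coefficients))
        rows.append((f.feature_id, f.family, f.intercept, b[0], b[1], f.r2_mod, f.p_value, q))
    return pd.DataFrame(
        rows,
        columns=["feature", "family", "intercept", "beta1", "beta2", "r2_mod", "p_value", "p_adjusted"],
    )


def wald_cluster_test(
    values: np.ndarray,
    pseudotime: np.ndarray,
    cluster_mask: np.ndarray,
    grid_size: int = 100,
    delta: float = 1.35,
    alpha: float = 0.05,
    feature_id: str = "feature",
    cluster: str = "cluster",
) -> WaldResult:
    """Wald test of whether a cluster's trend differs from the background trend.

    The trend family is selected on the cluster's cells; both the cluster and
    the background are refit with that family so coefficient vectors are
    conformable.  The contrast evaluates (cluster curve - background curve)
    at ``grid_size`` evenly spaced progression points; the quadratic form
    W = (C'b)' (C'VC)^+ (C'b) uses an eigendecomposition keeping eigenvalues
    above 1e-8, whose count is the chi-square degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    mask = np.asarray(cluster_mask, dtype=bool)
    if mask.sum() < 10 or (~mask).sum() < 10:
        raise ValueError("cluster and background each require at least 10 observations")
    p = standardize_pseudotime(pseudotime)
    sel = fit_trend_models(y[mask], p[mask], delta, alpha, feature_id)
    family = sel.family
    if family == "none":
        # fall back to the best-R^2 family so the curve contrast is defined
        fits = [_fit_family(p[mask], y[mask], fam, delta) for fam in _FAMILIES]
        family = max(fits, key=lambda f: f["r2_mod"])["family"]
    fit_c = _fit_family(p[mask], y[mask], family, delta)
    fit_b = _fit_family(p[~mask], y[~mask], family, delta)
    beta = np.concatenate([fit_c["beta"], fit_b["beta"]])
    k = fit_c["beta"].shape[0]
    vhat = np.zeros((2 * k, 2 * k))
    vhat[:k, :k] = fit_c["cov"]
    vhat[k:, k:] = fit_b["cov"]
    grid = np.linspace(0.0, 1.0, grid_size)
    basis = _design(grid, family)  # (n, k)
    c = np.vstack([basis.T, -basis.T])  # (2k, n)
    diff = c.T @ beta  # curve difference at grid points
    a = c.T @ vhat @ c  # (n, n)
    evals, evecs = np.linalg.eigh((a + a.T) / 2.0)
    keep = evals > 1e-8
    r = int(keep.sum())
    if r == 0:
        warnings.warn("contrast covariance is singular after thresholding; p = 1", stacklevel=2)
        return WaldResult(feature_id, cluster, 0.0, 0, 1.0, grid_size, family)
    proj = evecs[:, keep].T @ diff
    w = float(np.sum(proj**2 / evals[keep]))
    p_val = float(stats.chi2.sf(w, r))
    return WaldResult(feature_id, cluster, w, r, p_val, grid_size, family)


# ---------------------------------------------------------------------------
# Group comparisons


def welch_proportion_test(
    proportions: ProportionModel,
    groups: pd.Series | dict | np.ndarray,
    cluster: str,
    group_a: str | None = None,
    group_b: str | None = None,
) -> GroupTestResult:
    """Two-sided Welch t-test of a cluster's proportion between two sample groups."""
    if cluster not in proportions.cluster_names:
        raise ValueError(f"unknown cluster {cluster!r}")
    g = pd.Series(groups)
    g.index = g.index.astype(str)
    g = g.reindex(proportions.sample_ids)
    levels = sorted(g.dropna().unique().tolist())
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError("specify group_a and group_b when there are not exactly 2 groups")
        group_a, group_b = levels
    k = proportions.cluster_names.index(cluster)
    a = proportions.proportions[np.asarray(g == group_a), k]
    b = proportions.proportions[np.asarray(g == group_b), k]
    return welch_test(a, b, feature_id=cluster, group_a=str(group_a), group_b=str(group_b))


def welch_test(
    a: np.ndarray, b: np.ndarray, feature_id: str = "", group_a: str = "a", group_b: str = "b"
) -> GroupTestResult:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group requires at least 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    effect = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        t, dof, p = (0.0, float(a.size + b.size - 2), 1.0) if effect == 0 else (np.inf, 1.0, 0.0)
    else:
        se2 = va / a.size + vb / b.size
        t = effect / np.sqrt(se2)
        dof = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return GroupTestResult(
        feature_id=feature_id,
        group_a=group_a,
        group_b=group_b,
        statistic=float(t),
        dof=float(dof),
        p_value=p,
        effect=effect,
        test="welch",
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _squeeze_var(s2: np.ndarray, dof: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene variances toward a common prior.

    Fits an inverse-chi-square prior (d0, s0^2) to the observed variances by
    moment matching on log variances and returns the posterior variances
    (d0*s0^2 + dof*s2) / (d0 + dof) together with (d0, s0^2).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(dof / 2.0) + np.log(dof / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    resid_var = e_var - float(polygamma(1, dof / 2.0))
    if resid_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        return np.full_like(s2, s0_2), d0, s0_2
    d0 = 2.0 * _trigamma_inverse(resid_var)
    s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + dof * s2) / (d0 + dof)
    return post, d0, s0_2


def moderated_de_test(
    dataset: CellDataset,
    cluster: str,
    groups: pd.Series | dict,
    group_a: str | None = None,
    group_b: str | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test on cells of one cluster between two sample groups.

    Cells of the target cluster are split by their sample's group label.
    Gene-wise residual variances are shrunk toward a common prior estimated
    from the variance distribution; the moderated t uses residual + prior
    degrees of freedom.  ``prior_df`` forces the prior degrees of freedom
    (``np.inf`` reduces every gene to the common pooled variance).  Genes
    with zero variance in both groups are excluded and reported in the
    ``excluded`` DataFrame attribute.
    """
    g = pd.Series(groups)
    g.index = g.index.astype(str)
    levels = sorted(g.dropna().unique().tolist())
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError("specify group_a and group_b when there are not exactly 2 groups")
        group_a, group_b = levels
    cmask = dataset.cluster_of_cell == cluster
    if not cmask.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    cell_groups = g.reindex(dataset.sample_of_cell[cmask]).to_numpy()
    x = dataset.dense_features()[cmask]
    in_a = cell_groups == group_a
    in_b = cell_groups == group_b
    for name, m in ((group_a, in_a), (group_b, in_b)):
        n_samp = len(np.unique(dataset.sample_of_cell[cmask][m]))
        if n_samp < 2:
            raise ValueError(f"group {name!r} has cells from fewer than 2 samples in cluster {cluster!r}")
    xa, xb = x[in_a], x[in_b]
    na, nb = xa.shape[0], xb.shape[0]
    mean_diff = xa.mean(axis=0) - xb.mean(axis=0)
    dof = na + nb - 2
    s2 = (xa.var(axis=0, ddof=0) * na + xb.var(axis=0, ddof=0) * nb) / dof
    keep = s2 > 0
    excluded = [] if dataset.feature_names is None else [
        dataset.feature_names[j] for j in np.flatnonzero(~keep)
    ]
    names = (
        dataset.feature_names
        if dataset.feature_names is not None
        else [f"g{j}" for j in range(x.shape[1])]
    )
    s2k = s2[keep]
    if prior_df is None:
        post, d0, _ = _squeeze_var(s2k, dof)
    elif np.isinf(prior_df):
        d0 = np.inf
        post = np.full_like(s2k, float(s2k.mean()))
    else:
        d0 = float(prior_df)
        s0_2 = float(s2k.mean())
        post = (d0 * s0_2 + dof * s2k) / (d0 + dof)
    se = np.sqrt(post * (1.0 / na + 1.0 / nb))
    tmod = mean_diff[keep] / se
    df_total = dof + (0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        pvals = 2.0 * stats.norm.sf(np.abs(tmod))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tmod), df_total)
    out = pd.DataFrame(
        {
            "feature": [names[j] for j in np.flatnonzero(keep)],
            "effect": mean_diff[keep],
            "t": tmod,
            "dof": df_total,
            "p_value": pvals,
            "p_adjusted": bh_adjust(pvals),
        }
    ).sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    out.attrs["excluded"] = excluded
    out.attrs["prior_df"] = d0
    out.attrs["groups"] = (str(group_a), str(group_b))
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("p-values contain NaN")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Covariate association tests


def association_tests(
    result, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Associate a clustering or trajectory with per-sample covariates.

    Clustering labels vs. discrete covariates use a chi-square test of
    independence and vs. numeric covariates a one-way ANOVA; progression
    scores vs. discrete covariates use a one-way ANOVA and vs. numeric
    covariates a Spearman correlation test.  Covariates with a single level
    are skipped (reported with NaN statistics); p-values are BH-adjusted
    across the covariate family.
    """
    from pilot.clustering import SampleClustering
    from pilot.trajectory import TrajectoryResult

    if isinstance(result, SampleClustering):
        mode = "clustering"
        values = result.labels
    elif isinstance(result, TrajectoryResult):
        mode = "trajectory"
        values = result.progression
    else:
        raise TypeError("result must be a SampleClustering or TrajectoryResult")
    meta = metadata.copy()
    meta.index = meta.index.astype(str)
    meta = meta.reindex(result.sample_ids)
    if meta.isna().all(axis=None):
        raise ValueError("metadata does not cover the result's samples")
    rows = []
    for col in meta.columns:
        series = meta[col]
        numeric = pd.api.types.is_numeric_dtype(series)
        if series.dropna().nunique() < 2:
            rows.append((col, "skipped", np.nan, np.nan, np.nan))
            continue
        ok = series.notna().to_numpy()
        v = values[ok]
        s = series[ok]
        if mode == "clustering" and not numeric:
            table = pd.crosstab(v, s)
            stat, p, dof, _ = stats.chi2_contingency(table)
            rows.append((col, "chi2", float(stat), float(dof), float(p)))
        elif mode == "clustering" and numeric:
            groups = [s[v == lab].to_numpy(float) for lab in np.unique(v)]
            stat, p = stats.f_oneway(*groups)
            rows.append((col, "anova", float(stat), float(len(groups) - 1), float(p)))
        elif mode == "trajectory" and not numeric:
            groups = [v[(s == lev).to_numpy()].astype(float) for lev in s.unique()]
            stat, p = stats.f_oneway(*groups)
            rows.append((col, "anova", float(stat), float(len(groups) - 1), float(p)))
        else:
            rho, p = stats.spearmanr(v, s.to_numpy(float))
            rows.append((col, "spearman", float(rho), np.nan, float(p)))
    out = pd.DataFrame(rows, columns=["covariate", "test", "statistic", "dof", "p_value"])
    tested = out["test"] != "skipped"
    padj = np.full(len(out), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["p_adjusted"] = padj
    return out
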