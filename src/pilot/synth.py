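"""Synthetic multi-sample cohorts with planted trajectories or sample groups.

The generator emulates the structure of an integrated, clustered single-cell
(or pathomics) cohort: ``L`` samples each contribute a multinomial draw of
cells over ``K`` clusters, with cluster proportions following planted curves
of a latent per-sample time (trajectory scenario) or fixed per-group
compositions (groups scenario).  Cells live around well-separated cluster
centroids in an ``E``-dimensional embedding; gene values are a per-cluster
baseline plus optional planted polynomial trends of the latent time, Gaussian
noise and dropout-style zero inflation.  A single seeded generator drives all
randomness, so a config and seed fully determine the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pilot.dataset import CellDataset

# (base, linear, quadratic) coefficients of the default proportion curves;
# cycled over clusters.  All stay positive on [0, 1].
_DEFAULT_CURVES = [
    (1.0, 2.0, 0.0),  # linear increase
    (1.0, -0.9, 0.0),  # linear decrease
    (1.0, 0.0, 3.0),  # quadratic increase
    (1.0, 0.0, -0.9),  # quadratic decrease
    (1.0, 0.0, 0.0),  # constant
]


@dataclass
class SynthConfig:
    """Study conditions of the simulated cohort."""

    n_samples: int = 60
    n_clusters: int = 5
    cells_per_sample: tuple[int, int] = (2000, 2000)  # inclusive range
    embed_dim: int = 10
    n_genes: int = 50
    scenario: str = "trajectory"  # or "groups"
    n_groups: int = 3
    proportion_curves: list[tuple[float, float, float]] | None = None
    trend_genes: list[tuple[int, int, str, float]] | None = None  # (cluster, gene, family, effect)
    noise_sd: float = 0.5
    dropout_rate: float = 0.2
    centroid_sd: float = 3.0
    cell_sd: float = 0.5
    min_centroid_separation: float = 2.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted structure returned alongside the generated dataset."""

    planted_time: pd.Series | None  # per-sample latent time in [0, 1]
    group_labels: pd.Series | None
    trend_genes: list[tuple[str, str, str, float]]  # (cluster, gene, family, effect)
    proportions: pd.DataFrame  # planted per-sample cluster proportions


def _curve(base: float, a: float, b: float, t: np.ndarray) -> np.ndarray:
    return np.maximum(base + a * t + b * t**2, 1e-6)


def planted_proportions(config: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Per-sample cluster proportions implied by the planted curves at times t."""
    curves = config.proportion_curves or [
        _DEFAULT_CURVES[k % len(_DEFAULT_CURVES)] for k in range(config.n_clusters)
    ]
    if len(curves) != config.n_clusters:
        raise ValueError("one proportion curve per cluster is required")
    w = np.column_stack([_curve(b, a, q, t) for (b, a, q) in curves])
    return w / w.sum(axis=1, keepdims=True)


def _group_compositions(k: int, n_groups: int) -> np.ndarray:
    """Well-separated group compositions: each group dominated by its own clusters."""
    comp = np.ones((n_groups, k))
    for g in range(n_groups):
        comp[g, g % k] += 9.0
        comp[g, (g + 1) % k] += 4.0
    return comp / comp.sum(axis=1, keepdims=True)


def _draw_centroids(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    cents = []
    for _ in range(config.n_clusters):
        for _attempt in range(1000):
            c = rng.normal(0.0, config.centroid_sd, size=config.embed_dim)
            if all(np.linalg.norm(c - o) >= config.min_centroid_separation for o in cents):
                cents.append(c)
                break
        else:
            raise ValueError(
                "could not place cluster centroids with the requested separation; "
                "lower min_centroid_separation or raise centroid_sd/embed_dim"
            )
    return np.array(cents)


_TREND_BASIS = {
    "linear": lambda t: t,
    "quadratic": lambda t: t**2,
    "linear_quadratic": lambda t: t + t**2,
}


def generate_dataset(config: SynthConfig) -> tuple[CellDataset, GroundTruth]:
    """Generate a cohort with planted structure; returns (dataset, ground truth)."""
    if config.scenario not in ("trajectory", "groups"):
        raise ValueError("scenario must be 'trajectory' or 'groups'")
    rng = np.random.default_rng(config.seed)
    L, K = config.n_samples, config.n_clusters
    width = max(2, len(str(L - 1)))
    sample_names = [f"s{i:0{width}d}" for i in range(L)]
    kwidth = max(2, len(str(K - 1)))
    cluster_names = [f"c{k:0{kwidth}d}" for k in range(K)]
    gene_names = [f"g{j:03d}" for j in range(config.n_genes)]

    if config.scenario == "trajectory":
        t = np.linspace(0.0, 1.0, L)
        props = planted_proportions(config, t)
        time_series = pd.Series(t, index=sample_names, name="planted_time")
        group_series = None
    else:
        groups = np.array([g % config.n_groups for g in range(L)])
        comp = _group_compositions(K, config.n_groups)
        props = comp[groups]
        t = np.zeros(L)
        time_series = None
        group_series = pd.Series(
            [f"group{g}" for g in groups], index=sample_names, name="group"
        )

    centroids = _draw_centroids(rng, config)
    lo, hi = config.cells_per_sample
    n_cells = rng.integers(lo, hi + 1, size=L)
    counts = np.array([rng.multinomial(n_cells[l], props[l]) for l in range(L)])

    # planted gene trends: default plants one trend of each family in the
    # first three clusters on distinct genes
    trend_spec = config.trend_genes
    if trend_spec is None:
        trend_spec = [
            (0, 0, "linear", 2.0),
            (1 % K, 1 % config.n_genes, "quadratic", 2.0),
            (2 % K, 2 % config.n_genes, "linear_quadratic", 2.0),
        ]
    baselines = rng.normal(0.0, 1.0, size=(K, config.n_genes))

    samples, clusters, emb_rows, gene_rows = [], [], [], []
    for l in range(L):
        for k in range(K):
            m = counts[l, k]
            if m == 0:
                continue
            samples.extend([sample_names[l]] * m)
            clusters.extend([cluster_names[k]] * m)
            emb_rows.append(centroids[k] + rng.normal(0.0, config.cell_sd, size=(m, config.embed_dim)))
            g = np.tile(baselines[k], (m, 1))
            for ck, gj, fam, eff in trend_spec:
                if ck == k:
                    g[:, gj] += eff * _TREND_BASIS[fam](t[l])
            g += rng.normal(0.0, config.noise_sd, size=g.shape)
            if config.dropout_rate > 0:
                g[rng.random(g.shape) < config.dropout_rate] = 0.0
            gene_rows.append(g)
    embedding = np.vstack(emb_rows)
    features = np.vstack(gene_rows)

    metadata = pd.DataFrame(index=pd.Index(sample_names, name="sample"))
    if time_series is not None:
        metadata["planted_time"] = time_series
        metadata["status"] = np.where(t < 0.5, "early", "late")
    if group_series is not None:
        metadata["group"] = group_series

    dataset = CellDataset(
        features=features,
        sample_of_cell=np.array(samples),
        cluster_of_cell=np.array(clusters),
        embedding=embedding,
        feature_names=gene_names,
        sample_metadata=metadata,
    )
    truth = GroundTruth(
        planted_time=time_series,
        group_labels=group_series,
        trend_genes=[
            (cluster_names[ck], gene_names[gj], fam, eff) for ck, gj, fam, eff in trend_spec
        ],
        proportions=pd.DataFrame(props, index=sample_names, columns=cluster_names),
    )
    return dataset, truth
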