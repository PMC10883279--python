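import numpy as np
import pytest

from pilot import CellDataset
from pilot.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_trajectory_cohort():
    """Small cohort with a planted trajectory (12 samples, 5 clusters)."""
    cfg = SynthConfig(
        n_samples=12, cells_per_sample=(200, 200), n_genes=12, embed_dim=6, seed=3
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_groups_cohort():
    """Small cohort with 3 planted sample groups."""
    cfg = SynthConfig(
        n_samples=18, cells_per_sample=(300, 300), n_genes=12, embed_dim=6,
        scenario="groups", seed=4,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def toy_dataset():
    """Tiny hand-built dataset: 2 samples, 2 clusters, explicit embedding."""
    features = np.arange(40, dtype=float).reshape(20, 2)
    samples = np.array(["A"] * 10 + ["B"] * 10)
    clusters = np.array(["c1"] * 5 + ["c2"] * 5 + ["c1"] * 2 + ["c2"] * 8)
    embedding = np.tile([1.0, 0.0], (20, 1))
    embedding[clusters == "c2"] = [0.0, 1.0]
    return CellDataset(
        features=features,
        sample_of_cell=samples,
        cluster_of_cell=clusters,
        embedding=embedding,
    )
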