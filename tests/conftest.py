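import numpy as np
import pytest

from embedbench import NBSimConfig, preprocess, simulate_nb_counts


@pytest.fixture(scope="session")
def small_sim():
    """Small labeled NB dataset: 3 well-separated classes."""
    cfg = NBSimConfig(
        n_classes=3, cells_per_class=50, n_genes=80, marker_fraction=0.1,
        marker_log2_fc=3.0, seed=7,
    )
    counts = simulate_nb_counts(cfg)
    expr = preprocess(counts, pca_dim=20)
    return cfg, counts, expr


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_labeled_instance(rng, n_max=50, d_max=6, c_max=5):
    """Random labeled point set with every class having >= 2 members."""
    c = int(rng.integers(3, c_max + 1))
    n = int(rng.integers(max(2 * c, 12), n_max + 1))
    d = int(rng.integers(2, d_max + 1))
    while True:
        labels = rng.integers(0, c, n)
        counts = np.bincount(labels, minlength=c)
        if counts.min() >= 2:
            break
    return rng.normal(size=(n, d)), labels
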