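import numpy as np
import pandas as pd
import pytest

from orthoscreen.containers import CountMatrix, ReferenceSpec
from orthoscreen.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete simulated experiment config."""
    return SimConfig(
        n_null_genes=60,
        n_planted_genes=8,
        n_divergent_paralogs=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """High depth, huge NB size, zero profile noise: the exact-recovery limit."""
    return SimConfig(
        n_null_genes=120,
        n_planted_genes=10,
        n_divergent_paralogs=1,
        profile_noise_sd=0.0,
        dispersion=1e5,
        library_size_mean=2e7,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_config):
    return simulate_experiment(noiseless_config)


@pytest.fixture
def tiny_counts():
    """Two genes, four samples over two stages, hand-checkable totals."""
    counts = pd.DataFrame(
        [[100, 200, 0, 50], [900, 800, 1000, 950]],
        index=["g1", "g2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "species": ["x"] * 4,
            "stage": ["t1", "t1", "t2", "t2"],
            "replicate": [1, 2, 1, 2],
        }
    )
    return CountMatrix(counts, samples, stage_order=("t1", "t2"))


@pytest.fixture
def default_reference():
    return ReferenceSpec("Sox9", "sox9b", 0.7)


def textbook_pearson(x, y):
    """Independent plain-Python product-moment formula (test oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = (sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y)) ** 0.5
    return num / den
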