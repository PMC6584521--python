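import numpy as np
import pytest

import metann as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_table():
    """3 balanced classes x 15 samples x 30 OTUs, error-free counts."""
    cfg = m.SimulationConfig(
        n_classes=3,
        samples_per_class=15,
        n_otus=30,
        block_sizes=(10, 10, 10),
        block_dispersions=(0.5, 1.0, 10.0),
        seed=7,
    )
    return m.simulate_dataset(cfg)


@pytest.fixture
def tiny_counts():
    """Hand-sized labeled table for I/O and preprocessing checks."""
    counts = np.array([[2, 3, 5], [1, 0, 9], [4, 4, 2], [0, 1, 0]])
    sample_ids = [f"s{i}" for i in range(4)]
    otu_ids = ["otuA", "otuB", "otuC"]
    labels = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
    taxonomy = {
        "otuA": "Firmicutes;Bacilli",
        "otuB": "Bacteroidetes;Bacteroidia",
        "otuC": "Firmicutes;Clostridia",
    }
    return m.OTUTable(counts, sample_ids, otu_ids, taxonomy, labels)
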