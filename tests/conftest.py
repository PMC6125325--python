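import numpy as np
import pandas as pd
import pytest

import otuforest as of
from otuforest.tables import SAMPLE_ID_TOKEN


@pytest.fixture
def toy_table():
    """4 samples x 3 OTUs, handcrafted counts."""
    return pd.DataFrame(
        [[10, 0, 5], [2, 2, 0], [1, 0, 3], [4, 4, 4]],
        index=pd.Index(["s1", "s2", "s3", "s4"], name=SAMPLE_ID_TOKEN),
        columns=["OTU_A", "OTU_B", "OTU_C"],
        dtype=np.int64,
    )


@pytest.fixture
def toy_meta(toy_table):
    return pd.DataFrame(
        {
            "trial": ["T1", "T1", "T1", "T1"],
            "day": [35, 35, 7, 35],
            "group": ["control", "control", "treatment", "treatment"],
        },
        index=toy_table.index,
    )


@pytest.fixture
def toy_taxonomy():
    return pd.DataFrame(
        {
            "phylum": ["Firmicutes", "Firmicutes", "Bacteroidetes"],
            "class": ["c1", "c1", "c2"],
            "order": ["o1", "o1", "o2"],
            "family": ["f1", "f2", "f3"],
            "genus": ["g1", "g2", "g3"],
        },
        index=pd.Index(["OTU_A", "OTU_B", "OTU_C"], name="otu_id"),
    )


@pytest.fixture(scope="session")
def small_sim():
    """Two-trial community with two strongly planted OTUs (one up, one down)."""
    cfg = of.SimulationConfig(
        n_trials=2,
        n_per_group=12,
        n_otus=40,
        n_sensitive=2,
        effect_sizes=(8.0, 0.125),
        seed=11,
    )
    return of.simulate_community(cfg)


def random_count_table(rng, n_samples=None, n_otus=None):
    """Random small count table used by the conservation property tests."""
    n_samples = n_samples or int(rng.integers(2, 8))
    n_otus = n_otus or int(rng.integers(2, 12))
    counts = rng.integers(0, 50, size=(n_samples, n_otus))
    # keep row totals positive so composition ops are defined
    counts[:, 0] += 1
    return pd.DataFrame(
        counts,
        index=pd.Index([f"s{i}" for i in range(n_samples)], name=SAMPLE_ID_TOKEN),
        columns=[f"OTU_{j:03d}" for j in range(n_otus)],
        dtype=np.int64,
    )
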