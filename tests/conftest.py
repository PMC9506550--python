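import numpy as np
import pandas as pd
import pytest

from brachymet.featuretable import FeatureTable, canonical_design
from brachymet.library import load_compound_library
from brachymet.pathenrich import load_pathway_graph


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def pathway_graph():
    return load_pathway_graph()


def make_table(values: np.ndarray, seed: int = 0) -> FeatureTable:
    """Wrap a (features x 48) matrix in a FeatureTable on the canonical design."""
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    design = canonical_design()
    assert values.shape[1] == len(design)
    features = pd.DataFrame({
        "feature_id": [f"F{i:04d}" for i in range(n)],
        "mz": rng.uniform(100, 1000, n),
        "rt": rng.uniform(0.5, 12, n),
        "polarity": rng.choice(["positive", "negative"], n),
    })
    intensities = pd.DataFrame(values, index=features["feature_id"],
                               columns=design["sample_id"])
    return FeatureTable(features, design, intensities)


@pytest.fixture
def random_log2_table():
    rng = np.random.default_rng(42)
    t = make_table(rng.normal(14, 2, size=(50, 48)))
    t.transformed = "log2"
    return t
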