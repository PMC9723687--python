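import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rarescape import FeatureTable, SampleMetadata, read_tree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: four-tip balanced tree used throughout the hand-computed fixtures
BALANCED_NEWICK = "((A:1,B:1):2,(C:1,D:1):2);"


@pytest.fixture
def balanced_tree():
    return read_tree(io.StringIO(BALANCED_NEWICK))


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        {"S1": [5, 3, 2], "S2": [1, 0, 9]}, index=["A", "B", "C"]
    )
    return FeatureTable(counts)


@pytest.fixture
def small_metadata():
    frame = pd.DataFrame(
        {
            "sample_id": ["S1", "S2"],
            "stage": ["stage0", "stage0"],
            "time": ["time0", "time1"],
            "replicate": ["rep0", "rep0"],
        }
    ).set_index("sample_id")
    return SampleMetadata(frame)


def random_rarefied_table(rng, n_taxa=30, n_samples=6, depth=500):
    """Uniform-depth table with random multinomial composition."""
    w = rng.dirichlet(np.ones(n_taxa))
    counts = np.column_stack(
        [rng.multinomial(depth, w) for _ in range(n_samples)]
    )
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"T{i}" for i in range(n_taxa)],
            columns=[f"S{j}" for j in range(n_samples)],
        ),
        is_rarefied=True,
        depth=depth,
    )
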