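import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from eutromics.containers import OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    """2 sites x 2 OTUs with counts [[5, 0], [1, 3]]."""
    return OtuTable(
        pd.DataFrame([[5, 0], [1, 3]], index=["s1", "s2"], columns=["otuA", "otuB"])
    )


@pytest.fixture
def two_tip_tree() -> TreeNode:
    return TreeNode.read(["(A:1,B:1);"])


def random_table(
    rng: np.random.Generator, n_sites: int = 8, n_otus: int = 20, max_count: int = 50
) -> OtuTable:
    counts = rng.integers(0, max_count, size=(n_sites, n_otus))
    counts[:, 0] += 1  # keep every site total positive
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_sites)],
            columns=[f"o{j:03d}" for j in range(n_otus)],
        )
    )


@pytest.fixture
def table_factory():
    return random_table
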