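import numpy as np
import pandas as pd
import pytest

from chemophylo import parse_newick, simulate_tree


@pytest.fixture
def cherry3():
    """((A,B),C) with known path lengths."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule10():
    return simulate_tree(10, 1.0, seed=101)


@pytest.fixture
def yule100():
    return simulate_tree(100, 1.0, seed=2024)


def make_peak_table(rows):
    """rows: (species, sex, mating, replicate, feature, area)."""
    return pd.DataFrame(
        rows,
        columns=["species", "sex", "mating", "replicate", "feature", "area"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
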