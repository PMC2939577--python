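import numpy as np
import pytest

import divtempo as dt

#: 4-tip comb with splits at ages 3, 2, 1: x = (3,2,1), g = (1,1,1), T = 9.
COMB4 = "(((A:1,B:1):1,C:2):1,D:3);"

#: balanced 4-tip tree with splits at 3, 1, 1: x = (3,1,1), g = (2,0,1), T = 8.
BALANCED4 = "((A:1,B:1):2,(C:1,D:1):2);"


@pytest.fixture
def comb4():
    return dt.parse_newick(COMB4)


@pytest.fixture
def balanced4():
    return dt.parse_newick(BALANCED4)


@pytest.fixture(scope="session")
def random_trees():
    """A pool of simulated Yule chronograms of assorted sizes, used for
    property and limit-identity checks."""
    return [
        dt.simulate_yule(n, lam, seed)
        for seed, (n, lam) in enumerate(
            [(5, 1.0), (10, 0.5), (20, 0.2), (50, 0.1), (80, 0.3),
             (12, 2.0), (30, 0.05), (64, 1.0), (25, 0.4), (40, 0.15)]
        )
    ]


@pytest.fixture(scope="session")
def demo_bundle():
    """The packaged synthetic demo bundle (built once per session)."""
    return dt.harpaline_fixture(11)
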