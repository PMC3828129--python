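import numpy as np
import pytest

from foldspace.synth import random_tree


@pytest.fixture
def tree12():
    """Default 12-leaf three-superkingdom tree, seeded."""
    return random_tree({"Archaea": 4, "Bacteria": 4, "Eukarya": 4}, seed=1)


@pytest.fixture
def tree8():
    return random_tree({"Archaea": 2, "Bacteria": 3, "Eukarya": 3}, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
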