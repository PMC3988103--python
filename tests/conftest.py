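import numpy as np
import pytest

from scorpallo import default_cladogram, load_trait_table, vcv_from_tree


@pytest.fixture(scope="session")
def table1():
    """The bundled eight-species bothriurid trait table (log columns attached)."""
    return load_trait_table("vrech2014")


@pytest.fixture(scope="session")
def tree():
    return default_cladogram()


@pytest.fixture(scope="session")
def vbase(table1, tree):
    """Phylogenetic covariance of the default cladogram in table row order."""
    return vcv_from_tree(tree, tip_order=table1.species)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140415)
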