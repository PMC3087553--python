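import dendropy
import numpy as np
import pytest

from globkit.catalog import load_packaged_catalog
from globkit.simulate import PRESETS, make_mirage_gene


@pytest.fixture(scope="session")
def catalog():
    return load_packaged_catalog()


@pytest.fixture(scope="session")
def bflgb6_h1():
    return make_mirage_gene(PRESETS["bflgb6_h1"], gene_id="bflgb6_h1")


@pytest.fixture(scope="session")
def bflgb9():
    return make_mirage_gene(PRESETS["bflgb9"], gene_id="bflgb9")


@pytest.fixture()
def ladder_tree_8():
    return dendropy.Tree.get(data="(((((((a,b),c),d),e),f),g),h);", schema="newick")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
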