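import pytest

from exontile import DesignParams, design_array, make_unigene_set


@pytest.fixture
def params():
    return DesignParams()


@pytest.fixture(scope="session")
def unigene_50(
):
    """50 mutually 18-mer-disjoint random 1 kb genes (seed 1), no duplicates."""
    return make_unigene_set(
        n_genes=50, length_range=(1000, 1000), dup_fraction=0.0, seed=1
    )


@pytest.fixture(scope="session")
def design_50(unigene_50):
    """Default-parameter array design over the 50-gene session fixture."""
    return design_array(unigene_50.records)
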