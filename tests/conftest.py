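import pytest

from aldoprio.datasets import published_gene_cutoffs, published_variant_table


@pytest.fixture(scope="session")
def table1():
    """The packaged 21-variant published call set."""
    return published_variant_table()


@pytest.fixture(scope="session")
def cutoffs():
    return published_gene_cutoffs()
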