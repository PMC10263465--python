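import numpy as np
import pytest

import phlagraph
from phlagraph.aaindex import (
    build_embedding,
)
from phlagraph.graph import PseudoSequenceTable


@pytest.fixture(scope="session")
def embedding():
    """Residue embedding built from the packaged synthetic AAindex fixture."""
    return build_embedding(phlagraph.packaged_aaindex_path(), n_components=20)


@pytest.fixture(scope="session")
def pseudo_table():
    return PseudoSequenceTable.from_tsv(phlagraph.packaged_pseudo_path())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
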