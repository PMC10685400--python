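import numpy as np
import pytest
from hypothesis import settings

from stabiliforge.formats_io import Msa
from stabiliforge.synthetic import synth_structure

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix30():
    """30-residue ideal helix, seed 7 (shared read-only fixture)."""
    return synth_structure(30, seed=7)


@pytest.fixture()
def toy_msa():
    """Factory for small hand-written alignments (query row first)."""

    def build(rows, ids=None, query_id=None):
        ids = ids or [f"s{i}" for i in range(len(rows))]
        return Msa(ids=ids, rows=list(rows), query_id=query_id or ids[0])

    return build


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
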