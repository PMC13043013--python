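import numpy as np
import pytest

from cyanophot.pipeline import analyze_collection
from cyanophot.references import default_panel
from cyanophot.synthetic_data import generate_collection

#: fixed seed for the shared end-to-end collection
COLLECTION_SEED = 7


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def collection():
    """The default 14-metagenome synthetic collection (fixed seed)."""
    return generate_collection(rng_seed=COLLECTION_SEED)


@pytest.fixture(scope="session")
def bundle(collection):
    """Full pipeline result on the shared collection (computed once)."""
    return analyze_collection(
        collection.mags,
        qc=None,
        coverage=collection.coverage,
        taxonomy=collection.taxonomy,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
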