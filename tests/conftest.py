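import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirseeker.annotation_filters import ReferenceCollection, ReferenceRecord
from mirseeker.preprocess import AdapterSpec
from mirseeker.simulate import random_seq


@pytest.fixture
def rng():
    return np.random.default_rng(20110225)


@pytest.fixture
def adapters():
    return AdapterSpec()


@pytest.fixture
def small_contaminants(rng):
    """Tiny synthetic rRNA/tRNA decoy collection."""
    return ReferenceCollection(
        [
            ReferenceRecord("rrna1", random_seq(rng, 400), "barley", "rRNA"),
            ReferenceRecord("trna1", random_seq(rng, 200), "rice", "tRNA"),
            ReferenceRecord("sno1", random_seq(rng, 150), "wheat", "snoRNA"),
        ]
    )


@pytest.fixture
def small_repeats(rng):
    return ReferenceCollection(
        [ReferenceRecord("rep1", random_seq(rng, 600), "rice", "repeat")]
    )
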