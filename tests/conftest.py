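import numpy as np
import pytest

from cellstates.labels import LABEL_ORDER
from cellstates.phantoms import generate_field, generate_training_corpus


@pytest.fixture(scope="session")
def small_field():
    """One 1000x1000 phantom field with 12 cells, fixed seed."""
    image, truth = generate_field(12, seed=101)
    return image, truth


@pytest.fixture(scope="session")
def tiny_corpus():
    """Balanced 6x8 crop corpus, fixed seed."""
    crops, labels = generate_training_corpus(8, seed=202)
    return crops, labels


@pytest.fixture(scope="session")
def label_names():
    return [l.value for l in LABEL_ORDER]
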