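import numpy as np
import pytest

from lulcsim import CategoricalLandscape


def make_landscape(values, cell_size=30.0, labels=None, mask=None):
    values = np.asarray(values, dtype=np.int32)
    return CategoricalLandscape(values, mask, cell_size, labels or {})


@pytest.fixture
def forest_labels():
    return {1: "PF", 2: "SF", 3: "HS", 4: "AWV", 5: "WB"}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_landscape(rng, shape=(20, 20), codes=(1, 2, 3), cell_size=30.0):
    values = rng.choice(codes, size=shape).astype(np.int32)
    return CategoricalLandscape(values, None, cell_size, {c: str(c) for c in codes})
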