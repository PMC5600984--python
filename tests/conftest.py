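import numpy as np
import pytest

from ldpo import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def column_labels():
    """1-D GM | GWB GWB GWB | WM column as a (1,1,5) label volume."""
    lab = np.array([[[2, 4, 4, 4, 3]]], dtype=np.uint8)
    return Volume(lab, role="label")


def make_volume(data, role="intensity", spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data), spacing=spacing, role=role)


@pytest.fixture
def make_vol():
    return make_volume
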