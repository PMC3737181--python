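import numpy as np
import pytest

from ryrec import data


@pytest.fixture(scope="session")
def marker_map():
    return data.marker_map()


@pytest.fixture(scope="session")
def parents(marker_map):
    return [marker_map.haplotype("ry606N"), marker_map.haplotype("ry609N")]


@pytest.fixture()
def rng():
    return np.random.default_rng(20130801)
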