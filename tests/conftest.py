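import numpy as np
import pytest

from visrsa.geometry import ResponseMatrix
from visrsa.voxels import RunBetaSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_response_matrix(rng):
    return ResponseMatrix(values=rng.normal(size=(4, 6)),
                          condition_labels=["a", "b", "c", "d"])


@pytest.fixture
def small_beta_series(rng):
    return RunBetaSeries(betas=rng.normal(size=(4, 3, 5)),
                         condition_labels=["a", "b", "c"],
                         roi_name="V1")
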