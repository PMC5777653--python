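import numpy as np
import pytest

from dfcd.datatypes import BoldSeries, EventTrain
from dfcd import synth


def line_mask(n: int) -> np.ndarray:
    """n voxels laid out along one axis (coordinates for a (n,1,1) grid)."""
    return np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])


def make_bold(data: np.ndarray, tr: float) -> BoldSeries:
    """Wrap a voxel x time matrix as a BoldSeries on a line grid."""
    data = np.atleast_2d(np.asarray(data, float))
    n = data.shape[0]
    return BoldSeries(data=data, tr=tr, mask_index=line_mask(n),
                      space_shape=(n, 1, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def hrf():
    return synth.HrfModel()


@pytest.fixture
def single_event():
    return EventTrain(onsets=np.array([60.0]), durations=np.array([0.5]))


@pytest.fixture
def small_network():
    """Two 4-voxel clusters plus 4 background voxels on a 12-voxel line."""
    assign = np.array([1, 1, 1, 1, 2, 2, 2, 2, 0, 0, 0, 0])
    return synth.NetworkSpec(
        cluster_assignments=assign,
        coupling_amplitude={0: 0.0, 1: 1.0, 2: 0.5},
        noise_sd=1.0)
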