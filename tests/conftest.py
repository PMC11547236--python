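import numpy as np
import pytest

from bounti import BountiParams, IntensityVolume, make_phantom, two_body_spec

# thresholds bracketing the default phantom intensities
# (background 5000 < TT 27000 < bridge 30000 < IT 35000 < core 40000)
PHANTOM_IT = 35000
PHANTOM_TT = 27000


@pytest.fixture(scope="session")
def clean_two_body():
    """Noise-free, blur-free two-body phantom with its ground truth."""
    return make_phantom(two_body_spec())


@pytest.fixture
def phantom_params():
    return BountiParams(
        initial_threshold=PHANTOM_IT,
        target_threshold=PHANTOM_TT,
        num_iterations=10,
        num_segments=2,
    )


def random_volume(rng, max_edge=12, levels=(0, 100, 200, 300)):
    """Small random piecewise-level volume for oracle comparisons."""
    shape = tuple(int(rng.integers(3, max_edge + 1)) for _ in range(3))
    data = rng.choice(levels, size=shape).astype(np.uint16)
    return IntensityVolume(data)
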