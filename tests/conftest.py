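import numpy as np
import pytest

from mifind.simulate import PatternGenSpec, SubjectParams, null_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def subject():
    return SubjectParams()


@pytest.fixture
def small_spec():
    """A small pattern spec so per-test simulations stay fast."""
    return PatternGenSpec(n_voxels=20, trials_per_finger_imagery=16,
                          trials_per_finger_execution=12, residual_factor=5)


@pytest.fixture
def small_null_spec(small_spec):
    return null_spec(small_spec)
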