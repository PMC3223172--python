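import numpy as np
import pytest

from ctus_fusion.geometry import RigidTransform, make_transform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def true_calibration() -> RigidTransform:
    return make_transform((0.2, -0.1, 0.3), (10.0, -5.0, 2.0))


@pytest.fixture
def true_registration() -> RigidTransform:
    return make_transform((0.1, 0.05, -0.2), (25.0, -10.0, 40.0))


def random_transform(rng, angle_scale=np.pi / 2, trans_scale=50.0) -> RigidTransform:
    angles = rng.uniform(-angle_scale, angle_scale, size=3)
    t = rng.uniform(-trans_scale, trans_scale, size=3)
    return make_transform(angles, t)
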