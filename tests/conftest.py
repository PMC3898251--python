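import numpy as np
import pytest

from ssbridge.fixtures import BridgeSpec, build_ideal_bridge, build_survey_set


@pytest.fixture(scope="session")
def bridge():
    """Default planted bridge: chi3 = -87, chi1 = chi1' = -60, no noise."""
    return build_ideal_bridge(BridgeSpec())


@pytest.fixture(scope="session")
def bridge_model(bridge):
    return bridge[0]


@pytest.fixture(scope="session")
def gradient_model():
    model, _ = build_ideal_bridge(BridgeSpec(bfactor_plan="gradient"))
    return model


@pytest.fixture(scope="session")
def small_survey():
    """A dozen planted bridges for unit-level survey tests."""
    return build_survey_set(12, seed=7)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans
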