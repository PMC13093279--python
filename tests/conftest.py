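import numpy as np
import pytest

from surftrack.simulate import SceneConfig, make_layout, make_rig


@pytest.fixture(scope="session")
def scene_cfg() -> SceneConfig:
    return SceneConfig(seed=1)


@pytest.fixture(scope="session")
def rig(scene_cfg):
    return make_rig(scene_cfg)


@pytest.fixture(scope="session")
def abdominal_layout():
    return make_layout("abdominal")


@pytest.fixture(scope="session")
def hn_layout():
    return make_layout("hn")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
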