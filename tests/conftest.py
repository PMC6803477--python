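import numpy as np
import pytest

from canonloop.synthetic import LoopTemplate, make_loop


@pytest.fixture
def helix_template() -> LoopTemplate:
    return LoopTemplate("a1", [(-57.0, -47.0)] * 6)


@pytest.fixture
def cdr3_template() -> LoopTemplate:
    return LoopTemplate("b3", [(-139.0, 135.0)] * 9)


@pytest.fixture
def helix_loop(helix_template):
    return make_loop(helix_template, seed=7, sequence="ACDEFG", source="hx00:A")


@pytest.fixture
def cdr3_loop(cdr3_template):
    return make_loop(cdr3_template, seed=7, sequence="CASSLGTDT", source="cd00:B")


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(scale=10.0, size=3)
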