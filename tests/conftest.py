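import numpy as np
import pytest

from stageopt.search_space import ParamSpec, SearchSpace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_space():
    """Small mixed continuous/integer space for optimizer tests."""
    return SearchSpace(
        (
            ParamSpec("a", "continuous", -5.0, 5.0),
            ParamSpec("b", "continuous", 0.0, 1.0),
            ParamSpec("c", "integer", 1, 10),
        )
    )


@pytest.fixture
def box2d():
    """2-D continuous box centred on the origin."""
    return SearchSpace(
        (
            ParamSpec("x0", "continuous", -5.12, 5.12),
            ParamSpec("x1", "continuous", -5.12, 5.12),
        )
    )


@pytest.fixture(scope="session")
def tiny_images():
    """Small, well-separated synthetic image set for structural CNN tests."""
    from stageopt.synthetic_data import SyntheticImageSpec, make_images

    spec = SyntheticImageSpec(
        n_per_class=(30, 30, 30, 30), separability=3.0, seed=7
    )
    return make_images(spec)


@pytest.fixture(scope="session")
def easy_images():
    """High-separability image set at 200/class for learnability checks."""
    from stageopt.synthetic_data import SyntheticImageSpec, make_images

    spec = SyntheticImageSpec(
        n_per_class=(200, 200, 200, 200), separability=3.0, seed=0
    )
    return make_images(spec)
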