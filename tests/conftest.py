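import numpy as np
import pytest

from cuejudge.models import CAMParams, ExemplarPool
from cuejudge.task import CueProfile, TaskEnvironment, enumerate_profiles


@pytest.fixture(scope="session")
def add_env() -> TaskEnvironment:
    return TaskEnvironment(kind="additive")


@pytest.fixture(scope="session")
def mult_env() -> TaskEnvironment:
    return TaskEnvironment(kind="multiplicative")


@pytest.fixture(scope="session")
def all_profiles() -> list[CueProfile]:
    return enumerate_profiles()


@pytest.fixture(scope="session")
def true_cam() -> CAMParams:
    return CAMParams(15.0, (5.0, 4.0, 3.0, 2.0, 1.0))


@pytest.fixture(scope="session")
def full_pool(add_env, all_profiles) -> ExemplarPool:
    """All 32 profiles with their additive criteria."""
    return ExemplarPool(tuple((p, add_env.criterion(p)) for p in all_profiles))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
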