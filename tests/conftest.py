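import numpy as np
import pytest

from nfkbsync.model_core import BASELINE, ForcingSignal, KineticParameters
from nfkbsync.stability import ParameterPrior, randomize_parameters


@pytest.fixture(scope="session")
def baseline() -> KineticParameters:
    return BASELINE


@pytest.fixture(scope="session")
def constant_forcing() -> ForcingSignal:
    return ForcingSignal(kind="constant", S_high=2.0)


@pytest.fixture(scope="session")
def square_tf90() -> ForcingSignal:
    return ForcingSignal(kind="square", S_high=2.0, S_low=0.0, T1=45.0, T2=45.0)


@pytest.fixture(scope="session")
def square_tf180() -> ForcingSignal:
    # pulse protocol: 30 min dose, 150 min washout
    return ForcingSignal(kind="square", S_high=2.0, S_low=0.0, T1=30.0, T2=150.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def jittered_params(n: int, degree: float = 0.15, seed: int = 0) -> list[KineticParameters]:
    """Random parameter sets near the baseline (cell-to-cell scale jitter)."""
    prior = ParameterPrior(BASELINE, {k: degree for k in KineticParameters.RATE_NAMES})
    children = np.random.SeedSequence(seed).spawn(n)
    return [randomize_parameters(prior, np.random.default_rng(c)) for c in children]
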