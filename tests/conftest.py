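import numpy as np
import pytest

from sibsize import LambdaDistribution, default_lambda_distribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def skewed_lambda():
    """Reference age-structured f(lambda): strong parental variation."""
    return default_lambda_distribution(beta=0.9)


@pytest.fixture(scope="session")
def flat_lambda():
    """Reference f(lambda) with essentially no parental variation."""
    return default_lambda_distribution(beta=0.0009)


@pytest.fixture
def constant_lambda():
    return LambdaDistribution.constant(4.5)
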