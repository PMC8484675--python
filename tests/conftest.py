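import numpy as np
import pytest

from qmiseq import SurveyConfig, generate_survey, quantify_table


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic survey (seed 42), shared read-only across tests."""
    return generate_survey(SurveyConfig(seed=42))


@pytest.fixture(scope="session")
def quantified(bundle):
    qt, cals = quantify_table(bundle.read_table, bundle.standards, bundle.metadata)
    return qt, cals


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
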