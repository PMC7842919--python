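import numpy as np
import pytest

from paneval import (
    compute_entropy_weights,
    evaluate_rsr,
    evaluate_topsis,
    fixture_china_mch,
)


@pytest.fixture(scope="session")
def china_raw():
    return fixture_china_mch("raw")


@pytest.fixture(scope="session")
def china_cotrended():
    return fixture_china_mch("cotrended")


@pytest.fixture(scope="session")
def china_weights(china_raw):
    return compute_entropy_weights(china_raw)


@pytest.fixture(scope="session")
def china_topsis(china_raw, china_weights):
    return evaluate_topsis(china_raw, china_weights.weights)


@pytest.fixture(scope="session")
def china_rsr(china_raw, china_weights):
    return evaluate_rsr(china_raw, china_weights.weights)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
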