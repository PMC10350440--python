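import numpy as np
import pytest

from dietrisk import build_risk_table
from dietrisk.cli_io import ningxia_output_moments, ningxia_tables


@pytest.fixture(scope="session")
def tables():
    """(concentrations, exposure factors, toxicity references) packaged fixtures."""
    return ningxia_tables()


@pytest.fixture(scope="session")
def stats(tables):
    return tables[0]


@pytest.fixture(scope="session")
def factors(tables):
    return tables[1]


@pytest.fixture(scope="session")
def tox(tables):
    return tables[2]


@pytest.fixture(scope="session")
def risk_table(tables):
    return build_risk_table(*tables)


@pytest.fixture(scope="session")
def hi_moments():
    return ningxia_output_moments("hi")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
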