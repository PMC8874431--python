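import numpy as np
import pytest

from parvodyn import default_parameter_table


@pytest.fixture(scope="session")
def table1():
    """The bundled five-temperature parameter table."""
    return default_parameter_table()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
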