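import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fetiron import (
    KINETIC_CONSTANTS,
    TABLE1_CONSTANTS,
    get_o17_params,
    get_relax_params,
)


@pytest.fixture(scope="session")
def table1():
    return TABLE1_CONSTANTS


@pytest.fixture(scope="session")
def kinetic_model():
    return KINETIC_CONSTANTS


@pytest.fixture(scope="session")
def relax_fel2():
    return get_relax_params("FeL2")


@pytest.fixture(scope="session")
def relax_fel3():
    return get_relax_params("FeL3")


@pytest.fixture(scope="session")
def relax_fel1():
    return get_relax_params("FeL1")


@pytest.fixture(scope="session")
def o17_fel2():
    return get_o17_params("FeL2")


@pytest.fixture(scope="session")
def o17_fel1():
    return get_o17_params("FeL1")
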