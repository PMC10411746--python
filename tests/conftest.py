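import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from twopredprey import ModelParameters, find_equilibria


@pytest.fixture(scope="session")
def case1():
    return ModelParameters.from_preset("case1")


@pytest.fixture(scope="session")
def case2():
    return ModelParameters.from_preset("case2")


@pytest.fixture(scope="session")
def case4():
    return ModelParameters.from_preset("case4")


def equilibrium(params, tag):
    """Look up one equilibrium point by tag."""
    for point in find_equilibria(params):
        if point.tag == tag:
            return point
    raise LookupError(tag)
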