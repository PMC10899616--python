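import numpy as np
import pytest

from mietfcs import optics


@pytest.fixture(scope="session")
def emitter():
    return optics.Emitter()  # 680 nm, phi = 0.8, random orientation


@pytest.fixture(scope="session")
def objective():
    return optics.Objective()  # NA 1.49, oil 1.52


@pytest.fixture(scope="session")
def gold_stack():
    return optics.bare_gold()


@pytest.fixture(scope="session")
def graphene_stack():
    return optics.bare_graphene()


@pytest.fixture(scope="session")
def gold_calibration(emitter, objective, gold_stack):
    """Coarse-but-adequate calibration of the bare 10 nm gold scene,
    shared across tests (seconds to build)."""
    return optics.build_calibration(
        gold_stack, emitter, objective, np.linspace(0.5, 250.0, 180)
    )
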