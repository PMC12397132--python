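import numpy as np
import pytest

import dynpet as dp


@pytest.fixture(scope="session")
def schedule():
    return dp.make_default_schedule()


@pytest.fixture(scope="session")
def feng_inp():
    return dp.InputFunction.from_feng()


@pytest.fixture(scope="session")
def table1():
    return dp.load_reference_kinetic_params()


@pytest.fixture(scope="session")
def small_phantom():
    return dp.build_thorax_phantom((48, 48, 4))


@pytest.fixture(scope="session")
def liver_params(table1):
    r = table1.loc["liver"]
    return dp.KineticParams(r.K1, r.k2, r.k3, r.vb)
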