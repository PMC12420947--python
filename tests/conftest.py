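import numpy as np
import pytest

import poroperf as pp
from poroperf.workbench import make_fixture


@pytest.fixture(scope="session")
def y3():
    return make_fixture("y3")


@pytest.fixture(scope="session")
def bin4():
    return make_fixture("bin4")


@pytest.fixture(scope="session")
def cco200():
    """Seeded 200-terminal CCO tree in the 100 mm cube."""
    return make_fixture("cco200-seed1")


@pytest.fixture(scope="session")
def cco200_flow(cco200):
    return pp.solve_poiseuille(cco200, pp.FlowBCs.from_mmhg())


@pytest.fixture(scope="session")
def cube_mesh4():
    return pp.build_cube_mesh(4, 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
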