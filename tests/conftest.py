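import numpy as np
import pytest

import mechanofate as mf


@pytest.fixture(scope="session")
def unit_cube_mesh():
    return mf.build_hex_mesh((10.0, 10.0, 10.0), (1, 1, 1))


@pytest.fixture(scope="session")
def small_mesh():
    return mf.build_hex_mesh((20.0, 20.0, 20.0), (2, 2, 2))


@pytest.fixture(scope="session")
def cube_mesh():
    # 80 um cube at the standard 10 um resolution; big enough to hold a
    # centred cell with clearance
    return mf.build_hex_mesh((80.0, 80.0, 80.0), (8, 8, 8))


@pytest.fixture(scope="session")
def cube_op(cube_mesh):
    return mf.assemble_operator(cube_mesh, mf.MaterialProps(E=10.0))


@pytest.fixture(scope="session")
def params():
    return mf.MechanicalParams()


@pytest.fixture(scope="session")
def fate_params():
    return mf.FateParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A fast runnable configuration: quarter-size box, native resolution."""
    return mf.SimulationConfig(
        E=45.0, dims=(100.0, 100.0, 100.0), n_div=(10, 10, 10),
        n_steps=10, replicates=1, seed=0,
    )
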