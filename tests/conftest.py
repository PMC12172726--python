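import numpy as np
import pytest

from tdcsphere.geometry import build_atlas, build_head_model, layout_1020
from tdcsphere.montages import montage_library


@pytest.fixture(scope="session")
def head():
    return build_head_model()


@pytest.fixture(scope="session")
def layout(head):
    return layout_1020(head)


@pytest.fixture(scope="session")
def atlas_mesh(head):
    return build_atlas(head, n_nodes=2000)


@pytest.fixture(scope="session")
def atlas(atlas_mesh):
    return atlas_mesh[0]


@pytest.fixture(scope="session")
def mesh(atlas_mesh):
    return atlas_mesh[1]


@pytest.fixture(scope="session")
def library(layout):
    return montage_library(layout)


@pytest.fixture(scope="session")
def hd_montage(library):
    return next(m for m in library if m.id == "hd_uniform_F3")


@pytest.fixture(scope="session")
def bipolar_montage(library):
    return next(m for m in library if m.id == "bipolar_F3_F4")


@pytest.fixture(scope="session")
def hd_field(head, hd_montage, mesh):
    from tdcsphere.solver import solve_field

    return solve_field(head, hd_montage, mesh)


@pytest.fixture(scope="session")
def bipolar_field(head, bipolar_montage, mesh):
    from tdcsphere.solver import solve_field

    return solve_field(head, bipolar_montage, mesh)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
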