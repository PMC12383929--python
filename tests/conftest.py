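import pytest

from tearsim.blink import BlinkSchedule
from tearsim.drainage import DrainageParams
from tearsim.geometry import build_mesh, derive_geometry
from tearsim.transport import DrugProperties


@pytest.fixture(scope="session")
def geometry():
    return derive_geometry()


@pytest.fixture(scope="session")
def mesh(geometry):
    return build_mesh(geometry)


@pytest.fixture(scope="session")
def schedule():
    return BlinkSchedule()


@pytest.fixture(scope="session")
def drainage_params():
    return DrainageParams()


@pytest.fixture(scope="session")
def drug():
    return DrugProperties()
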