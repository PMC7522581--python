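import numpy as np
import pytest

import petmrsim as pm


@pytest.fixture(scope="session")
def scanner() -> pm.ScannerGeometry:
    return pm.build_scanner()


@pytest.fixture(scope="session")
def digitizer_no_deadtime() -> pm.DigitizerConfig:
    return pm.DigitizerConfig(dead_time_tau_ns=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def f18() -> pm.IsotopeSpec:
    return pm.get_isotope("F18")


@pytest.fixture(scope="session")
def rb82() -> pm.IsotopeSpec:
    return pm.get_isotope("Rb82")


@pytest.fixture(scope="session")
def soft_cube() -> pm.World:
    return pm.build_tissue_cube("soft")


@pytest.fixture(scope="session")
def lung_cube() -> pm.World:
    return pm.build_tissue_cube("lung")
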