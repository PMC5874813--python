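import pytest

from ecollim import ElectronBeamModel, MachineGeometry, TrimmerMaterial


@pytest.fixture(scope="session")
def machine():
    return MachineGeometry()


@pytest.fixture(scope="session")
def beam():
    return ElectronBeamModel()


@pytest.fixture(scope="session")
def beam_fe():
    """Pure Fermi-Eyges gap term (no upstream-divergence moment)."""
    return ElectronBeamModel(air_term="fermi_eyges")


@pytest.fixture(scope="session")
def material():
    return TrimmerMaterial()


@pytest.fixture(scope="session")
def material_csda():
    return TrimmerMaterial(range_law="csda_table")
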