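import pytest

from tadrive import DriveArchitecture, DriveSystem, RateParams


@pytest.fixture
def tade_supp_arch():
    """TADE suppression drive with a failed rescue element (as observed)."""
    return DriveArchitecture(DriveSystem.TADE_SUPPRESSION, rescue_functional=False)


@pytest.fixture
def tade_mod_arch():
    return DriveArchitecture(DriveSystem.TADE_MODIFICATION, rescue_functional=False)


@pytest.fixture
def tade_ideal_arch():
    """Idealized functional TADE modification drive."""
    return DriveArchitecture(DriveSystem.TADE_MODIFICATION, rescue_functional=True)


@pytest.fixture
def tare_arch():
    return DriveArchitecture(DriveSystem.TARE, rescue_functional=True)


@pytest.fixture
def fly_params():
    """Rates inferred for the suppression-drive crosses."""
    return RateParams(c_germline=0.10, c_embryo=0.02, baseline_viability=0.83)
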