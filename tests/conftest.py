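import pytest

from tptcr.masses import IonSpecies
from tptcr.simulate import (
    ACBP_MASS,
    ALPHA_GLOBIN_HEME_MASS,
    APO_FABP1_MASS,
    COMPLEX_MASS,
    AcquisitionConfig,
    generate_phantom,
)
from tptcr.targeted import build_target_table


@pytest.fixture(scope="session")
def liver_species():
    """(name, mass, precursor charge) of the four-protein targeted panel."""
    return [
        ("FABP1+bezafibrate", COMPLEX_MASS, 8),
        ("heme-alpha-globin", ALPHA_GLOBIN_HEME_MASS, 8),
        ("apo-FABP1", APO_FABP1_MASS, 8),
        ("ACBP", ACBP_MASS, 6),
    ]


@pytest.fixture(scope="session")
def liver_target_table(liver_species):
    return build_target_table(liver_species, n_reduced=2)


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64x64 dosed phantom at 2 h post-dose."""
    return generate_phantom(seed=11)


@pytest.fixture
def ptcr_cfg():
    """Acquisition model for the PTCR product region (low resolution)."""
    return AcquisitionConfig(mz_range=(1500.0, 3600.0), resolving_power=1000.0, noise_sigma=2.0)


@pytest.fixture
def complex_ion():
    return IonSpecies("FABP1+bezafibrate", COMPLEX_MASS, 8)
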