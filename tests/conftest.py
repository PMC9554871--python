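import pytest

from psiqnmr import AcquisitionParams, SpeciesComposition
from psiqnmr.synthetic import default_assignments, internal_standard_umol


@pytest.fixture(scope="session")
def composition():
    return SpeciesComposition()


@pytest.fixture(scope="session")
def quiet_acq():
    """Noiseless acquisition with full relaxation."""
    return AcquisitionParams(noise_sigma=0.0)


@pytest.fixture(scope="session")
def assignments():
    return default_assignments()


@pytest.fixture(scope="session")
def amounts(composition):
    """Species amounts for a 1 mg sample with 0.4 mg of internal standard."""
    return {
        "APS-residue": composition.amine_loading_umol_per_mg,
        "PEG": 0.0,
        "impurity": composition.impurity_scale,
        "internal_standard": internal_standard_umol(0.4),
    }
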