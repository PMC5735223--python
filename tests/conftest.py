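import numpy as np
import pytest

from crossfeed.model_core import Capabilities, SpeciesParams
from crossfeed.reference import (
    reference_calibrations,
    reference_interactions,
    reference_model,
    reference_species,
)
from crossfeed.synthetic_data import CultureDesign


@pytest.fixture(scope="session")
def ref_species():
    return reference_species()


@pytest.fixture(scope="session")
def ref_interactions():
    return reference_interactions()


@pytest.fixture(scope="session")
def ref_calibrations():
    return reference_calibrations()


@pytest.fixture
def bi_mono_model():
    return reference_model(("Bi",))


@pytest.fixture
def pair_model():
    return reference_model(("Bi", "Ec"))


@pytest.fixture
def full_model():
    return reference_model()


@pytest.fixture
def simple_producer():
    """Producer of both acids with every loss channel disabled: death,
    maintenance and uptake all zero, so analytic yield identities hold."""
    return SpeciesParams(
        name="P", mu_max=0.8, K_s=0.1, Y_sx=0.3, Y_a=0.3, Y_l=0.2,
        I_a=20.0, I_l=20.0, k_d=0.0, t_lag=0.0, m_s=0.0,
        capabilities=Capabilities(produces_acetate=True, produces_lactate=True))


@pytest.fixture
def dense_mono_design():
    """2-h sampling to 36 h: the parameter-recovery fixture."""
    return CultureDesign(name="mono-Bi-dense", members=("Bi",),
                         times=tuple(np.arange(0.0, 36.1, 2.0)),
                         replicates=1, inoculum={"Bi": 0.01})
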