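import numpy as np
import pytest

from mesoid.elasticity import IsotropicModuli, isotropic_compliance
from mesoid.grids import StructuredGrid
from mesoid.random_field import FieldSpec


@pytest.fixture(scope="session")
def bone_moduli():
    """Mean moduli of the 2D validation material (GPa)."""
    return IsotropicModuli(13.75, 3.587)


@pytest.fixture(scope="session")
def compliance_spec(bone_moduli):
    """2D-plane-problem compliance field spec at delta=0.4, ell=125 um."""
    mean = isotropic_compliance(bone_moduli, form="full3d")
    return FieldSpec(mean=mean, delta=0.4, ell=(125e-6, 125e-6), seed=42)


@pytest.fixture(scope="session")
def meso_grid():
    """16x16 window grid at 4 cells per correlation length (h=31.25 um)."""
    return StructuredGrid((16, 16), (31.25e-6, 31.25e-6))


@pytest.fixture(scope="session")
def reduced_specimen():
    """One reduced-scale synthetic experiment (generated once per session)."""
    from mesoid.insilico import generate_specimen, reduced_validation_config

    return generate_specimen(reduced_validation_config(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)
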