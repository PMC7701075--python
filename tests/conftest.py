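import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fibrilhydro import FibrilMaterial, SolventConditions
from fibrilhydro.distribution_engine import WeightedDistribution
from fibrilhydro.fixtures import generate_afm_lengths

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def material():
    """Densified fibril material (2% over native BLG)."""
    return FibrilMaterial()


@pytest.fixture(scope="session")
def native_material():
    """Native BLG density, no densification."""
    return FibrilMaterial(densification=1.0)


@pytest.fixture(scope="session")
def solvent():
    return SolventConditions()


@pytest.fixture(scope="session")
def afm_lengths():
    """Reference AFM-like length sample: 2000 records, mean 395 nm."""
    return generate_afm_lengths(n=2000, seed=1234)


@pytest.fixture(scope="session")
def lognormal_length_dist():
    """Smooth mass-weighted lognormal length density on a fine grid
    (median 370 nm, shape 0.32), trapezoid-normalised."""
    grid = np.linspace(80.0, 1200.0, 512)
    med, shape = 370.0, 0.32
    dens = np.exp(-((np.log(grid) - np.log(med)) ** 2) / (2 * shape**2)) / grid
    dist = WeightedDistribution("length", grid, dens, "mass")
    return dist.normalized()
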