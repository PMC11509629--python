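import pytest

from bluntfit import IndenterGeometry, Material, TipFamily


@pytest.fixture
def cone_25_20():
    """MLCT-like sharp lever: half-angle 25 deg, apex radius 20 nm."""
    return IndenterGeometry(TipFamily.SPHERO_CONICAL, R=20e-9, theta_deg=25.0)


@pytest.fixture
def cone_35_20():
    return IndenterGeometry(TipFamily.SPHERO_CONICAL, R=20e-9, theta_deg=35.0)


@pytest.fixture
def cone_35_200():
    """Simulation-protocol geometry: half-angle 35 deg, apex radius 200 nm."""
    return IndenterGeometry(TipFamily.SPHERO_CONICAL, R=200e-9, theta_deg=35.0)


@pytest.fixture
def pyramid_35_200():
    return IndenterGeometry(TipFamily.BLUNTED_PYRAMID, R=200e-9, theta_deg=35.0, k=4)


@pytest.fixture
def soft_gel():
    """Incompressible 20 kPa half-space (the simulated-sample material)."""
    return Material(E=20e3, nu=0.5)


@pytest.fixture
def unit_reduced():
    """Material with unit reduced modulus, for F/E* (reduced-force) curves."""
    return Material.from_reduced(1.0, nu=0.0)
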