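import pytest

from plasmoflow import FluidProperties, TubeGeometry, WindkesselElement


@pytest.fixture
def cytoplasm():
    """Cytoplasm material properties: density, viscosity, wall modulus."""
    return FluidProperties(density=1120.0, viscosity=0.275, youngs_modulus=5200.0)


@pytest.fixture
def vein_geometry():
    """Typical internal vein segment: a = 20 um, l = 500 um, d = 70 um."""
    return TubeGeometry(radius=20e-6, length=500e-6, diameter=70e-6)


@pytest.fixture
def fluidic_element():
    """Fluidic element of one vein segment with 50x leakage resistance."""
    r1 = 2.188380467513560e15
    return WindkesselElement(r1=r1, r2=50 * r1, c=2.4166097335306106e-16,
                             unit_system="fluidic")


@pytest.fixture
def electrical_element():
    """Electrical twin used for circuit simulation: 10 Ohm, 500 Ohm, 0.053 F."""
    return WindkesselElement(r1=10.0, r2=500.0, c=0.053, unit_system="electrical")
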