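import numpy as np
import pytest
from hypothesis import settings

from torsplit import PeriodicPotential, RotorParams, synth_double_well

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cos3_potential():
    """Threefold rotor barrier V = 50 (1 - cos 3 tau), barrier 100 cm^-1."""
    return PeriodicPotential(a0=50.0, a=np.array([0.0, 0.0, -50.0]), b=np.zeros(3))


@pytest.fixture(scope="session")
def symmetric_well():
    """Two equivalent wells 104 deg apart across a 150 cm^-1 barrier."""
    return synth_double_well(barrier=150.0, asymmetry=0.0, well_separation=104.0, n_background=4)


@pytest.fixture(scope="session")
def asymmetric_well():
    """Same landscape with a 9 cm^-1 well-energy offset."""
    return synth_double_well(barrier=150.0, asymmetry=9.0, well_separation=104.0, n_background=4)


@pytest.fixture(scope="session")
def hydroxy_rotor():
    """Light hydroxy-torsion inertia (protiated)."""
    return RotorParams(reduced_moment=0.8, isotope_label="H")


@pytest.fixture(scope="session")
def methyl_rotor():
    """Methyl-like torsional inertia; slow tunneling regime."""
    return RotorParams(reduced_moment=3.2, isotope_label="CH3")


def low_ts_angle(pot):
    """Angle of the low separating barrier of a synthetic two-well fixture."""
    maxima = [p for p in pot.known_stationary_points if p.kind == "maximum"]
    return min(maxima, key=lambda p: p.energy).angle
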