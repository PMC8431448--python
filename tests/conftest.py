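import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from molstack.topology import AtomSpec, Frame, MoleculeSpec, Topology

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def point_molecule(name="X", mass=12.011, element="C"):
    """Single-atom molecule for contact/COM geometry tests."""
    return MoleculeSpec(species="pt", atoms=[AtomSpec(name=name, element=element, mass=mass)])


def point_topology(n):
    return Topology([point_molecule() for _ in range(n)])


def frame_of(points, box=100.0):
    return Frame(coordinates=np.asarray(points, dtype=float), box=np.full(3, float(box)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
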