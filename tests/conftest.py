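import numpy as np
import pytest

from cysloopvar import (
    ProteinSequence,
    ToyChannelSpec,
    fixtures,
    gen_toy_pentamer,
    make_toy_topology,
    packaged_topology,
)


@pytest.fixture(scope="session")
def gabra2_topology():
    return packaged_topology()["P47869"]


@pytest.fixture(scope="session")
def registry():
    return fixtures()


@pytest.fixture(scope="session")
def toy_topology():
    return make_toy_topology()


@pytest.fixture()
def toy_channel():
    """Default three-ring C5 channel plus its analytic profile."""
    spec = ToyChannelSpec()
    structure, analytic = gen_toy_pentamer(spec)
    return spec, structure, analytic


@pytest.fixture(scope="session")
def random_protein():
    rng = np.random.default_rng(20260923)
    residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400))
    return ProteinSequence(id="ref", residues=residues)


def station_radius(profile, structure_point):
    """Radius at the profile station nearest to a world-coordinate point."""
    origin = np.array(profile.origin)
    direction = np.array(profile.direction)
    s = float((np.asarray(structure_point) - origin) @ direction)
    idx = int(np.argmin(np.abs(profile.s_values() - s)))
    step = profile.steps[idx]
    assert step.defined
    return step.radius
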