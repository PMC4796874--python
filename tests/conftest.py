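import numpy as np
import pytest

import focuswalk as fw


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def born_ion():
    return fw.make_born_ion(1.0, 2.0)


@pytest.fixture
def random_structure(rng):
    """50 pseudo-atoms with random charges in a 10 Å ball around the origin."""
    n = 50
    coords = rng.uniform(-10, 10, size=(n, 3))
    charges = rng.uniform(-1, 1, size=n)
    return fw.from_arrays(coords, charges=charges, radii=np.full(n, 1.6),
                          lj_epsilon=np.full(n, 0.1), lj_sigma=np.full(n, 3.2),
                          label="random50")


@pytest.fixture
def tiny_lattice():
    """A small dense 6D lattice: 3x3x3 stations x structured 2x2x2 angles."""
    return fw.generate_lattice(
        "cuboidal",
        ranges={"x": (0, 2), "y": (0, 2), "z": (0, 2)},
        steps={"x": 1.0, "y": 1.0, "z": 1.0},
        rotamers={
            "ranges": {"phi": (0.0, 0.5), "theta": (0.1, 0.6), "psi": (0.0, 0.5)},
            "steps": {"phi": 0.5, "theta": 0.5, "psi": 0.5},
        },
    )


@pytest.fixture
def flat_1d_table():
    """Flat-energy 1D lattice of 41 stations, 4 Å apart."""
    lat = fw.generate_lattice("cuboidal", ranges={"z": (-80, 80)}, steps={"z": 4.0},
                              rotamers=1)
    n = lat.n_poses
    return fw.EnergyTable(lattice=lat, e_coul=np.zeros(n), e_solv=np.zeros(n),
                          e_vdw=np.zeros(n))
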