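import numpy as np
import pytest

from domaindyn.structio import ATOMIC_MASSES, Structure
from domaindyn.synthetic import make_two_domain_structure


def build_chain(first_resid=24, last_resid=109, chain="A", spacing=3.8):
    """Toy extended chain with full backbone per residue."""
    names, elements, resids, xyz = [], [], [], []
    offsets = {"N": (-1.0, 0.3, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (1.0, 0.3, 0.0), "O": (1.3, 1.4, 0.0)}
    for k, rid in enumerate(range(first_resid, last_resid + 1)):
        base = np.array([spacing * k, 0.2 * (k % 2), 0.0])
        for nm, off in offsets.items():
            names.append(nm)
            elements.append("N" if nm == "N" else ("O" if nm == "O" else "C"))
            resids.append(rid)
            xyz.append(base + np.array(off))
    n = len(names)
    return Structure(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids, dtype=int),
        resnames=np.array(["GLY"] * n),
        chains=np.array([chain] * n),
        coords=np.array(xyz, dtype=float),
        masses=np.array([ATOMIC_MASSES[e] for e in elements]),
        title="toy chain",
    )


def random_rigid(rng):
    """A random proper rotation matrix and translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(0, 2**31 - 1)))).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


@pytest.fixture
def toy_chain():
    return build_chain()


@pytest.fixture
def two_domain():
    return make_two_domain_structure(10, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
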