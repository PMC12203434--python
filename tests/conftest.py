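import numpy as np
import pytest

from adld.fixtures import make_cluster, make_dimer, make_hetero_dimer, make_ring
from adld.geometry import Atom, Molecule


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cluster():
    """10 carbon atoms, rejection-sampled, reproducible."""
    return make_cluster(10, "C", min_dist=1.8, box=6.0, seed=42)


@pytest.fixture
def contact_dimer():
    """Two 6-rings of carbon 4 A apart (CN-coupled at this separation)."""
    return make_dimer(make_ring(6, "C", 1.39), r=4.0)


@pytest.fixture
def li_ring_complex():
    """Carbon 6-ring with a lithium atom 2.5 A above its center."""
    ring = make_ring(6, "C", 1.39)
    li = Molecule([Atom("Li", np.zeros(3))])
    return make_hetero_dimer(ring, li, r=2.5)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diagonal(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
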