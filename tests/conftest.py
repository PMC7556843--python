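import numpy as np
import pytest

from ubisax.chain import BeadChain


def make_bead_chain(positions, residues=None, domains=None, backbone=None,
                    bead_class="BB"):
    """Minimal BeadChain from bare coordinates (nm)."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    residues = np.arange(1, n + 1) if residues is None else np.asarray(residues)
    domains = np.zeros(n, dtype=int) if domains is None else np.asarray(domains)
    backbone = np.ones(n, dtype=bool) if backbone is None else np.asarray(backbone)
    classes = np.array([bead_class] * n, dtype=object)
    return BeadChain(pos, residues, domains, classes, backbone)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
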