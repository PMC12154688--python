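import numpy as np
import pytest
from hypothesis import settings

from chromhet import CellConformation, ConformationEnsemble

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


def make_cell(cell_id, positions, genomic_size=10_000, radius=0.05):
    positions = np.asarray(positions, dtype=float)
    L = len(positions)
    return CellConformation(
        cell_id=cell_id,
        positions=positions,
        radii=np.full(L, radius),
        genomic_sizes=np.full(L, genomic_size),
    )


@pytest.fixture
def two_cell_ensemble():
    """Two cells x five beads with simple deterministic geometry."""
    c1 = make_cell("c1", [[i, 0.0, 0.0] for i in range(5)])
    c2 = make_cell("c2", [[0.0, 2.0 * i, 0.0] for i in range(5)])
    return ConformationEnsemble(cells=[c1, c2], length_unit="micron",
                                avg_bead_genomic_size=10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rigid_motion(rng):
    """A uniform random rotation (QR-based) plus a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return Q, t
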