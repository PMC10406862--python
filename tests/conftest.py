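import numpy as np
import pytest

from sonar.data import SpatialDataset
from sonar.simulate import make_synthetic_reference


@pytest.fixture(scope="session")
def tiny_reference():
    """Small 3-type synthetic scRNA-seq reference shared across tests."""
    counts, labels = make_synthetic_reference(
        n_types=3, n_genes=60, n_cells_per_type=20, n_markers_per_type=8,
        depth_mean=300, seed=7,
    )
    return counts, labels


@pytest.fixture(scope="session")
def toy_signature():
    """Deterministic 2-type x 5-gene signature with clear markers."""
    return np.array(
        [
            [5.0, 1.0, 0.2, 0.0, 1.0],
            [0.2, 1.0, 5.0, 2.0, 1.0],
        ]
    )


def lattice_dataset(counts, side, spacing=1.0, gene_ids=None):
    """Wrap a counts matrix on a square side x side lattice."""
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([cc.ravel(), rr.ravel()]) * spacing
    return SpatialDataset(counts=counts, coords=coords, gene_ids=gene_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
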