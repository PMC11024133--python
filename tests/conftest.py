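import numpy as np
import pytest

from spade.model import SingleCellDataset, SpatialDataset
from spade.simulate import standard_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sc() -> SingleCellDataset:
    """3 genes x 4 cells, two cell types with disjoint expressed genes."""
    counts = np.array(
        [
            [3, 1, 0, 0],
            [1, 3, 0, 0],
            [0, 0, 2, 6],
        ]
    )
    return SingleCellDataset(
        gene_ids=["gA", "gB", "gC"],
        cell_ids=["c1", "c2", "c3", "c4"],
        counts=counts,
        cell_type=["A", "A", "B", "B"],
        sample_id=["s0", "s1", "s0", "s1"],
    )


@pytest.fixture
def tiny_spatial() -> SpatialDataset:
    counts = np.array([[4, 0], [2, 1], [0, 5]])
    return SpatialDataset(
        gene_ids=["gA", "gB", "gC"],
        spot_ids=["s1", "s2"],
        counts=counts,
        coords=np.array([[0.0, 0.0], [0.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """8x8 grid, 2 domains, 4 types: fast end-to-end material."""
    return standard_benchmark(
        seed=7, grid=(8, 8), n_domains=2, n_types=4, cells_per_spot=20
    )
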