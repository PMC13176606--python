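import numpy as np
import pytest

from stimpute.data import (
    ExpressionMatrix,
    PairedDataset,
    SpatialCoordinates,
    build_shared_map,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix(rng):
    """8 cells x 5 genes of small random counts, no zero rows/columns."""
    values = rng.poisson(3.0, size=(8, 5)).astype(float) + 1.0
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(5)], [f"c{i}" for i in range(8)]
    )


@pytest.fixture
def tiny_pair(rng):
    """A small paired dataset with partial gene overlap and coordinates."""
    st_genes = ["A", "B", "C", "D"]
    sc_genes = ["B", "C", "D", "E", "F"]
    st = ExpressionMatrix(
        rng.poisson(4.0, size=(12, 4)).astype(float) + 1.0,
        st_genes, [f"st{i}" for i in range(12)],
    )
    sc = ExpressionMatrix(
        rng.poisson(4.0, size=(15, 5)).astype(float) + 1.0,
        sc_genes, [f"sc{i}" for i in range(15)],
    )
    coords = SpatialCoordinates(rng.uniform(size=(12, 2)))
    return PairedDataset(st=st, sc=sc, shared=build_shared_map(st, sc), st_coords=coords)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated pair shared by training-level tests (seeded)."""
    from stimpute.preprocess import preprocess_pair
    from stimpute.simulate import SimConfig, simulate_pair

    cfg = SimConfig(n_st_cells=220, n_sc_cells=300, n_genes_total=80,
                    latent_rank=4, seed=7)
    pair, truth = simulate_pair(cfg)
    return preprocess_pair(pair), truth
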