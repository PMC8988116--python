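import numpy as np
import pytest

from phaseasm.overlap import build_overlap_matrix, to_cost_matrix
from phaseasm.simdata import simulate_dataset


@pytest.fixture(scope="session")
def clean_cov10():
    """Error-free 50x3000 dataset at coverage 10 plus its matrices (shared:
    the overlap matrix is the expensive part)."""
    layout = simulate_dataset(length=15000, n_reads=50, read_len=3000,
                              overlap=2700, error_pct=0.0, seed=1)
    om = build_overlap_matrix(layout.reads)
    cm = to_cost_matrix(om)
    return layout, om, cm


@pytest.fixture(scope="session")
def small_layout():
    """A fast 12-read toy dataset (coverage ~4) for structural tests."""
    return simulate_dataset(length=1200, n_reads=12, read_len=400,
                            overlap=300, error_pct=0.0, seed=7)


def random_symmetric_cost(n: int, rng: np.random.Generator, high: int = 1000) -> np.ndarray:
    """Random integer (n+1)x(n+1) cost matrix with a zero-cost depot at index 0."""
    blk = rng.integers(0, high, size=(n, n))
    blk = (blk + blk.T) // 2
    np.fill_diagonal(blk, 0)
    c = np.zeros((n + 1, n + 1), dtype=np.int64)
    c[1:, 1:] = blk
    return c
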