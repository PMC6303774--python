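"""Shared fixtures: hand-built trees, lattice cells, and a GRF sampler."""

import dendropy
import numpy as np
import pandas as pd
import pytest


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def three_tip_tree():
    """Sisters A, B at depth 1 under a root at depth 2: d(A,B)=2, d(*,C)=4."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry_tree():
    return tree_from_newick("(A:1,B:1);")


@pytest.fixture
def five_tip_tree():
    """Ultrametric 5-tip tree with unequal node ages for enumeration oracles."""
    return tree_from_newick("(((A:1,B:1):1.5,C:2.5):1.5,(D:3,E:3):1);")


def lattice_cells(rows: int, cols: int, size: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [(c + 0.5) * size for r in range(rows) for c in range(cols)],
            "y": [(r + 0.5) * size for r in range(rows) for c in range(cols)],
            "area": size * size,
        },
        index=[f"c{i:03d}" for i in range(rows * cols)],
    )


class GRFSampler:
    """Gaussian random fields with exponential covariance on a lattice.

    The Cholesky factor is computed once per (shape, range) so Monte-Carlo
    calibration loops stay cheap.
    """

    def __init__(self, rows: int, cols: int, corr_range: float):
        self.coords = np.array(
            [[c + 0.5, r + 0.5] for r in range(rows) for c in range(cols)], float
        )
        n = rows * cols
        d = np.sqrt(((self.coords[:, None, :] - self.coords[None, :, :]) ** 2).sum(-1))
        cov = np.exp(-d / corr_range) + 1e-10 * np.eye(n)
        self.chol = np.linalg.cholesky(cov)
        self.n = n

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.chol @ rng.standard_normal(self.n)


@pytest.fixture(scope="session")
def grf_10x10():
    """Fields with range = lattice size / 3 (strong autocorrelation)."""
    return GRFSampler(10, 10, 10 / 3)
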