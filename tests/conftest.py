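import numpy as np
import pytest

from ilr import (
    IlrConfig,
    LabeledDataset,
    SimulationConfig,
    SplitSpec,
    normalize_dataset,
    simulate_counts,
    split_train_test,
)


def make_dataset(matrix, labels, gene_ids=None, cell_ids=None) -> LabeledDataset:
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    return LabeledDataset(
        matrix,
        gene_ids or [f"g{j}" for j in range(m)],
        cell_ids or [f"c{i}" for i in range(n)],
        np.asarray(labels, dtype=int),
    )


def gaussian_two_class(n_per_class, n_genes, n_informative, shift, seed=0) -> LabeledDataset:
    """Two Gaussian clouds separated by `shift` on the first genes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_genes))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, :n_informative] += shift
    perm = rng.permutation(n)
    return make_dataset(X[perm], y[perm])


@pytest.fixture(scope="session")
def small_sim():
    """A 300-cell, 200-gene simulated dataset with clear DE signal."""
    return simulate_counts(SimulationConfig(n_cells=300, n_genes=200, de_scale=0.6, seed=11))


@pytest.fixture(scope="session")
def small_split(small_sim):
    ds = normalize_dataset(small_sim.to_labeled_dataset())
    return split_train_test(ds, SplitSpec(0.8, True, 7))


@pytest.fixture(scope="session")
def fast_config():
    return IlrConfig(cv_folds=3, seed=0)
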