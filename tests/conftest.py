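import warnings

import numpy as np
import pytest

from cooccur import SimulationConfig, fit_transform, sample_ground_truth, simulate_counts
from cooccur.crossval import derive_seed


@pytest.fixture(autouse=True)
def _quiet_solver_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", message=".*Objective did not converge.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_synthetic(seed, n=120, d=10, density=0.2, sparsity=0.35):
    """Count table with known ground truth, plus its transformed matrix."""
    truth = sample_ground_truth(d, density, derive_seed(seed, "truth"))
    table = simulate_counts(
        truth,
        SimulationConfig(n_samples=n, n_taxa=d, edge_density=density,
                         target_sparsity=sparsity, seed=derive_seed(seed, "counts")),
    )
    data = fit_transform(table.counts).values
    return truth, table, data


@pytest.fixture
def small_synthetic():
    return make_synthetic(seed=0)
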