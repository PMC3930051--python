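import numpy as np
import pytest

from aflpscape.datatypes import BandMatrix
from aflpscape.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default survey design."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def tiny_matrix():
    """Hand-written 6-individual, 4-locus matrix over two populations."""
    vals = np.array([
        [1, 0, 1, 1],
        [1, 1, 0, 1],
        [0, 0, 1, 1],
        [0, 1, 1, 0],
        [0, 1, 0, 0],
        [1, 1, 1, 0],
    ], dtype=float)
    return BandMatrix(
        vals,
        [f"i{k}" for k in range(6)],
        ["A", "A", "A", "B", "B", "B"],
        ["L1", "L2", "L3", "L4"],
    )


def neutral_config(seed, n_loci=200, fst=0.07, n_pops=9, n_ind=15):
    """Single-level island-like neutral scenario used by calibration tests."""
    return SimulationConfig(
        n_clusters=1, pops_per_cluster=n_pops, n_admixed=0,
        n_individuals_per_pop=n_ind, n_loci=n_loci,
        F_CT=0.0, F_SC=fst, n_selected_loci=0,
        missing_rate=0.0, n_replicate_pairs=0, seed=seed,
    )
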