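import numpy as np
import pandas as pd
import pytest

from binqtl import experiments, simdata
from binqtl.matrix import MISSING, GenotypeMatrix


def make_matrix(parent_calls, offspring_calls, chrom=None, pos=None):
    """Small GenotypeMatrix from explicit parental and offspring call rows.

    ``parent_calls``: (m, 2) codes; ``offspring_calls``: (m, n) codes.
    """
    parent_calls = np.asarray(parent_calls, dtype=np.int8)
    offspring_calls = np.asarray(offspring_calls, dtype=np.int8)
    m = parent_calls.shape[0]
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    markers = pd.DataFrame(
        {"name": [f"Pp{c:02d}_{p}" for c, p in zip(chrom, pos)], "chrom": chrom, "pos": pos}
    )
    individuals = ["P1", "P2"] + [f"F1_{i+1:03d}" for i in range(offspring_calls.shape[1])]
    calls = np.concatenate([parent_calls, offspring_calls], axis=1)
    return GenotypeMatrix(markers, individuals, calls, parents=("P1", "P2"))


@pytest.fixture(scope="session")
def small_population():
    """Two-chromosome noisy F1 population: (truth, observed matrix)."""
    config = simdata.SimConfig(
        n_progeny=60,
        chrom_lengths=(10_000_000, 10_000_000),
        marker_density=10.0,
        map_length_morgans=0.5,
        marker_class_probs=(0.4, 0.4, 0.2),
        error_rate=0.01,
        missing_rate=0.05,
        seed=11,
    )
    return simdata.simulate_population(config)


@pytest.fixture(scope="session")
def clean_bc():
    """Error-free single-chromosome 1:1 dataset: (truth, sf matrix)."""
    return experiments.simulate_bc_dataset(
        seed=7,
        n_progeny=50,
        chrom_lengths=(10_000_000,),
        markers_per_mb=2.0,
        map_length_cm=50.0,
        error_rate=0.0,
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def bin_experiment():
    """Binned vs naive map lengths at the reference conditions
    (N=100, ~500 markers, 50 cM, 1% error, 5% missing)."""
    return experiments.binned_vs_naive_map(seed=1)
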