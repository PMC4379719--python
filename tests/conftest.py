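import numpy as np
import pytest

from netgp.genotypes import RawGenotypeTable
from netgp.simulate import SimConfig, simulate_dataset


@pytest.fixture
def toy_table() -> RawGenotypeTable:
    """4 samples x 3 markers; marker m2 is monomorphic (MAF 0), m1/m3 have MAF 0.5."""
    counts = np.array(
        [
            [0, 0, 2],
            [2, 0, 0],
            [0, 0, 2],
            [2, 0, 0],
        ],
        dtype=float,
    )
    return RawGenotypeTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        marker_ids=["m1", "m2", "m3"],
        counts=counts,
    )


@pytest.fixture(scope="session")
def additive_dataset():
    """Mid-sized additive trait shared across read-only tests."""
    return simulate_dataset(
        SimConfig(n_individuals=200, n_markers=120, h2=0.5, n_qtl=30, seed=42)
    )
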