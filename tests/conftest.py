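import numpy as np
import pytest

from farmcpu.simulate import SimulationConfig, simulate_dataset
from farmcpu.store import MarkerInfo, MarkerMatrix, from_array


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(array, tmp_path=None, sample_ids=None):
    """In-memory MarkerMatrix (or file-backed when tmp_path given)."""
    array = np.asarray(array, dtype=np.float64)
    ids = sample_ids or [f"s{i}" for i in range(array.shape[0])]
    if tmp_path is not None:
        return from_array(array, ids, tmp_path / "geno.bin")
    return MarkerMatrix(np.asfortranarray(array), ids)


def make_info(m, chrom=None, positions=None):
    return MarkerInfo(
        name=np.array([f"snp{j}" for j in range(m)], dtype=object),
        chromosome=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        position=np.array(
            positions if positions is not None else np.arange(1, m + 1) * 100
        ),
    )


@pytest.fixture
def small_dataset():
    """500 x 400 panel with 5 QTNs at h2 = 0.7."""
    config = SimulationConfig(n=500, m=400, n_qtn=5, h2=0.7, seed=7)
    matrix, info, trait = simulate_dataset(config)
    return matrix, info, trait
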