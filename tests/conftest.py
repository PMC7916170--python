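import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nudimine.simulate import build_reference_model, simulate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_protein(rng, length: int) -> str:
    return "M" + "".join(np.array(list(AA))[rng.integers(0, 20, size=length - 1)])


def random_dna(rng, length: int) -> str:
    return "".join(np.array(list(NT))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture(scope="session")
def ref_model():
    return build_reference_model(n_genes=30, genome_length=40_000, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full synthetic study reused across integration tests."""
    return simulate_dataset(
        n_genes=15, genome_length=20_000, n_fragments=4, min_gap=30,
        gene_loss_rate=0.0, n_host=10, host_length_range=(300, 1500),
        coverage=10, seed=0,
    )
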