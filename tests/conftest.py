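import numpy as np
import pytest

from mitojack.alignment import SiteMatrix
from mitojack.simulate import simulate_genome


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic dipluran-like genome with its truth table."""
    return simulate_genome(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def nt_matrix(taxa, rows, gene="g"):
    """Helper: SiteMatrix from aligned nucleotide strings."""
    return SiteMatrix.from_sequences(list(taxa), list(rows), gene)


@pytest.fixture()
def toy_matrix():
    return nt_matrix(["A", "B", "C", "D"],
                     ["ATGAAA", "ATGAAA", "ATGCCC", "ATGCCC"])
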