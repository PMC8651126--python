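import numpy as np
import pytest

from virtax import synth, taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_taxonomy_set():
    """2 families x 2 genera x 2 genomes, reduced gene complement (fast)."""
    genomes, truth = synth.gen_taxonomy_set(
        n_families=2, genera_per_family=2, genomes_per_genus=2,
        family_core=8, genus_core=8, private_genes=4, seed=42)
    return genomes, truth


@pytest.fixture(scope="session")
def small_classification(small_taxonomy_set):
    genomes, truth = small_taxonomy_set
    return taxonomy.classify(genomes), genomes, truth


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
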