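import numpy as np
import pytest

from snare_profiler import CorpusSpec, build_matrix, load_snarer_panel, random_corpus


@pytest.fixture(scope="session")
def panel():
    return load_snarer_panel()


@pytest.fixture(scope="session")
def small_corpus():
    """A small balanced corpus with the default Q/R composition signal."""
    records, labels = random_corpus(CorpusSpec(n_pos=20, n_neg=20, length=(40, 80), seed=11))
    return records, labels


@pytest.fixture(scope="session")
def gaac_matrix(small_corpus):
    records, labels = small_corpus
    return build_matrix(records, labels, "gaac")


def random_protein(rng: np.random.Generator, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
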