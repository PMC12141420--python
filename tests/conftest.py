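import numpy as np
import pytest

from littopics.preprocess import CleaningConfig, DocTermMatrix, Vocabulary
from littopics.synthetic import SimulationConfig, generate_corpus

import scipy.sparse as sp


@pytest.fixture(scope="session")
def small_corpus():
    """Small LDA corpus with known truth, shared across fast tests."""
    config = SimulationConfig(K_true=3, V=60, D=60, mean_doc_length=40, seed=11)
    return generate_corpus(config)


@pytest.fixture(scope="session")
def recovery_corpus():
    """The recovery-scale corpus: K_true=5, V=500, D=500, mean length 100."""
    config = SimulationConfig(
        K_true=5, V=500, D=500, mean_doc_length=100.0,
        alpha_true=0.1, beta_true=0.01, seed=101)
    return generate_corpus(config)


def toy_dtm(counts_array, terms=None):
    counts_array = np.asarray(counts_array)
    D, V = counts_array.shape
    if terms is None:
        terms = [f"t{j:03d}" for j in range(V)]
    vocab = Vocabulary(list(terms), (counts_array > 0).sum(axis=0))
    return DocTermMatrix(
        counts=sp.csr_matrix(counts_array),
        doc_ids=[f"d{i:03d}" for i in range(D)],
        vocabulary=vocab)


@pytest.fixture
def permissive_config():
    """Cleaning config that keeps every term (no rare-term filter)."""
    return CleaningConfig(min_doc_frequency=1)
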