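"""Collapsed Gibbs sampler: exact conditional oracle, perplexity oracles,
determinism, exchangeability and cross-validation contracts."""

import hashlib
import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from littopics.lda import (
    LDA,
    collapsed_conditional,
    cross_validate_k,
    log_joint,
    perplexity,
    DEFAULT_K_GRID,
)
from conftest import toy_dtm


# ---------------------------------------------------------------------------
# exact enumeration oracle for the collapsed conditional

def oracle_log_joint(z, docs, K, V, alpha, beta):
    """Collapsed log p(w, z) by direct evaluation of the Dirichlet-
    multinomial products; independent of the package implementation."""
    n_dk = np.zeros((len(docs), K))
    n_kv = np.zeros((K, V))
    pos = 0
    for d, words in enumerate(docs):
        for w in words:
            n_dk[d, z[pos]] += 1
            n_kv[z[pos], w] += 1
            pos += 1
    total = 0.0
    for k in range(K):
        total += gammaln(V * beta) - V * gammaln(beta)
        for v in range(V):
            total += gammaln(n_kv[k, v] + beta)
        total -= gammaln(n_kv[k].sum() + V * beta)
    for d in range(len(docs)):
        total += gammaln(K * alpha) - K * gammaln(alpha)
        for k in range(K):
            total += gammaln(n_dk[d, k] + alpha)
        total -= gammaln(n_dk[d].sum() + K * alpha)
    return total


def test_collapsed_conditional_matches_exhaustive_enumeration():
    """On a 2-document, 3-word, K=2 instance the sampler's conditional
    p(z_i = k | z_-i, w) must equal the ratio of exhaustively enumerated
    collapsed joints to 1e-12."""
    docs = [[0, 1, 2, 0], [1, 2]]
    K, V = 2, 3
    alpha, beta = 0.3, 0.5
    words = [w for d in docs for w in d]
    doc_of = [d for d, ws in enumerate(docs) for _ in ws]
    N = len(words)
    max_err = 0.0
    for z_rest in itertools.product(range(K), repeat=N):
        z = np.array(z_rest)
        for i in range(N):
            # oracle: condition by enumeration of the joint over z_i
            logps = []
            for k in range(K):
                z_i = z.copy()
                z_i[i] = k
                logps.append(oracle_log_joint(z_i, docs, K, V, alpha, beta))
            logps = np.array(logps)
            expect = np.exp(logps - logps.max())
            expect /= expect.sum()
            # implementation: conditional from counts excluding token i
            n_dk = np.zeros((len(docs), K))
            n_kv = np.zeros((K, V))
            for j in range(N):
                if j != i:
                    n_dk[doc_of[j], z[j]] += 1
                    n_kv[z[j], words[j]] += 1
            got = collapsed_conditional(
                n_dk[doc_of[i]], n_kv[:, words[i]], n_kv.sum(axis=1),
                alpha, beta, V)
            max_err = max(max_err, np.abs(got - expect).max())
    assert max_err <= 1e-12


def test_log_joint_agrees_with_oracle():
    docs = [[0, 1, 2, 0], [1, 2]]
    K, V = 2, 3
    rng = np.random.default_rng(0)
    z = rng.integers(0, K, size=6)
    n_dk = np.zeros((2, K))
    n_kv = np.zeros((K, V))
    pos = 0
    for d, ws in enumerate(docs):
        for w in ws:
            n_dk[d, z[pos]] += 1
            n_kv[z[pos], w] += 1
            pos += 1
    assert log_joint(n_dk, n_kv, 0.3, 0.5) == pytest.approx(
        oracle_log_joint(z, docs, K, V, 0.3, 0.5), abs=1e-10)


# ---------------------------------------------------------------------------
# perplexity

def test_uniform_predictor_perplexity_equals_vocabulary_size():
    V, K = 6, 3
    phi = np.full((K, V), 1.0 / V)
    heldout = toy_dtm(np.array([[2, 1, 0, 3, 1, 1], [1, 1, 1, 0, 2, 0]]))
    assert perplexity(phi, heldout, alpha=0.5, seed=0) == pytest.approx(V, abs=1e-10)


def test_single_word_vocabulary_perplexity_is_one():
    # K >= 2 topics over a single-term vocabulary: phi rows are all [1.0]
    phi = np.ones((2, 1))
    heldout = toy_dtm(np.array([[4], [2]]))
    assert perplexity(phi, heldout, alpha=0.1) == pytest.approx(1.0, abs=1e-12)


def _stream_seed(seed, doc_id):
    # documented per-document stream key, reproduced independently
    h = hashlib.blake2b(doc_id.encode(), digest_size=8).digest()
    return (int.from_bytes(h, "big") ^ (seed * 0x9E3779B97F4A7C15)) % (2**63)


def oracle_perplexity(phi, counts, doc_ids, alpha, seed, n_foldin):
    """Straight-line re-implementation of document-completion perplexity:
    plain loops, no vectorisation, shared only the documented stream key."""
    K, V = phi.shape
    total, n_eval = 0.0, 0
    for row in range(counts.shape[0]):
        toks = []
        for v in range(V):
            toks.extend([v] * int(counts[row, v]))
        foldin = toks[0::2]
        evaltoks = toks[1::2]
        gen = np.random.Generator(np.random.PCG64(
            _stream_seed(seed, "heldout:" + doc_ids[row])))
        ndk = [0.0] * K
        if foldin:
            zf = []
            u = gen.random(len(foldin))
            for i, v in enumerate(foldin):
                p = [phi[k, v] for k in range(K)]
                s = sum(p)
                c, k = 0.0, 0
                for kk in range(K):
                    c += p[kk] / s
                    if c >= u[i]:
                        k = kk
                        break
                else:
                    k = K - 1
                zf.append(k)
                ndk[k] += 1
            for _ in range(n_foldin):
                for i, v in enumerate(foldin):
                    ndk[zf[i]] -= 1
                    p = [(ndk[k] + alpha) * phi[k, v] for k in range(K)]
                    s = sum(p)
                    r = gen.random()
                    c, knew = 0.0, K - 1
                    for kk in range(K):
                        c += p[kk] / s
                        if c > r:
                            knew = kk
                            break
                    zf[i] = knew
                    ndk[knew] += 1
        theta = [(ndk[k] + alpha) / (sum(ndk) + K * alpha) for k in range(K)]
        for v in evaltoks:
            total += np.log(sum(theta[k] * phi[k, v] for k in range(K)))
            n_eval += 1
    return float(np.exp(-total / n_eval))


def test_perplexity_matches_straight_line_oracle():
    rng = np.random.default_rng(5)
    K, V = 3, 6
    phi = rng.dirichlet(np.ones(V), size=K)
    counts = rng.integers(0, 4, size=(4, V))
    counts[counts.sum(axis=1) == 0, 0] = 1
    dtm = toy_dtm(counts)
    got = perplexity(phi, dtm, alpha=0.4, seed=9, n_foldin=20)
    want = oracle_perplexity(phi, counts, dtm.doc_ids, 0.4, seed=9, n_foldin=20)
    assert got == pytest.approx(want, abs=1e-10)


# ---------------------------------------------------------------------------
# sampler behaviour

class TestFit:
    def test_single_word_corpus_puts_mass_on_it(self):
        # every document is "w" repeated: phi must put all non-smoothing
        # mass on that word and it must rank first in every topic
        counts = np.zeros((4, 3), dtype=int)
        counts[:, 1] = 5
        dtm = toy_dtm(counts, terms=["aaa", "bbb", "ccc"])
        dtm = dtm  # all-zero columns are fine; rows must be non-zero
        res = LDA(dtm, K=2, alpha=0.5, beta=0.01).fit(n_iter=20, burn_in=10, seed=0)
        assert (res.phi[:, 1] > 0.97).all()
        for ranked in res.top_words(2):
            assert ranked[0][0] == "bbb"

    def test_strong_prior_gives_near_uniform_theta(self):
        counts = np.array([[3, 2, 1]])
        dtm = toy_dtm(counts)
        res = LDA(dtm, K=2, alpha=1e5, beta=0.1).fit(n_iter=30, burn_in=10, seed=1)
        assert np.allclose(res.theta, 0.5, atol=1e-3)

    def test_zero_row_rejected(self):
        counts = np.array([[1, 0], [0, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            LDA(toy_dtm(counts), K=2)

    def test_counts_conserved_and_consistent_with_z(self, small_corpus):
        from littopics.preprocess import clean_corpus, CleaningConfig
        records, _ = small_corpus
        dtm, _ = clean_corpus(records, CleaningConfig(min_doc_frequency=2))
        res = LDA(dtm.fitted(), K=3, alpha=0.2, beta=0.1).fit(
            n_iter=15, burn_in=5, seed=2)
        lengths = np.asarray(dtm.fitted().counts.sum(axis=1)).ravel()
        assert (res.n_dk.sum(axis=1) == lengths).all()
        assert res.n_dk.sum() == res.z.shape[0]
        # recompute counts from z directly
        n_kv = np.zeros_like(res.n_kv)
        np.add.at(n_kv, (res.z, res.token_word), 1)
        assert (n_kv == res.n_kv).all()

    def test_rows_stochastic(self, small_corpus):
        from littopics.preprocess import clean_corpus, CleaningConfig
        records, _ = small_corpus
        dtm, _ = clean_corpus(records, CleaningConfig(min_doc_frequency=2))
        res = LDA(dtm.fitted(), K=4, alpha=0.3, beta=0.05).fit(
            n_iter=10, burn_in=5, seed=3)
        assert np.abs(res.phi.sum(axis=1) - 1).max() < 1e-10
        assert np.abs(res.theta.sum(axis=1) - 1).max() < 1e-10
        assert res.phi.min() > 0

    def test_seed_determinism_bit_identical(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(12, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dtm = toy_dtm(counts)
        r1 = LDA(dtm, K=3, alpha=0.2, beta=0.1).fit(n_iter=25, burn_in=10, seed=42)
        r2 = LDA(dtm, K=3, alpha=0.2, beta=0.1).fit(n_iter=25, burn_in=10, seed=42)
        assert (r1.z == r2.z).all()
        assert (r1.phi == r2.phi).all()
        assert (r1.theta == r2.theta).all()
        r3 = LDA(dtm, K=3, alpha=0.2, beta=0.1).fit(n_iter=25, burn_in=10, seed=43)
        assert not (r3.z == r1.z).all()

    def test_document_permutation_permutes_theta_rows(self):
        """Per-document random streams: shuffling the input rows yields the
        identically shuffled theta (exchangeability)."""
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, size=(10, 7))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dtm = toy_dtm(counts)
        perm = rng.permutation(10)
        from littopics.preprocess import DocTermMatrix
        shuffled = DocTermMatrix(
            counts=dtm.counts[perm],
            doc_ids=[dtm.doc_ids[i] for i in perm],
            vocabulary=dtm.vocabulary)
        r1 = LDA(dtm, K=3, alpha=0.2, beta=0.1).fit(n_iter=20, burn_in=5, seed=7)
        r2 = LDA(shuffled, K=3, alpha=0.2, beta=0.1).fit(n_iter=20, burn_in=5, seed=7)
        assert np.array_equal(r1.theta[perm], r2.theta)
        assert np.array_equal(r1.phi, r2.phi)

    def test_loglik_trace_finite_and_moving(self, small_corpus):
        from littopics.preprocess import clean_corpus, CleaningConfig
        records, _ = small_corpus
        dtm, _ = clean_corpus(records, CleaningConfig(min_doc_frequency=2))
        res = LDA(dtm.fitted(), K=3, alpha=0.2, beta=0.1).fit(
            n_iter=30, burn_in=10, seed=0)
        assert np.isfinite(res.loglik_trace).all()
        assert len(set(np.round(res.loglik_trace, 6))) > 1

    def test_averaged_estimates_option(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=(8, 6))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dtm = toy_dtm(counts)
        res = LDA(dtm, K=2, alpha=0.3, beta=0.1).fit(
            n_iter=30, burn_in=10, seed=0, average_every=5)
        assert np.abs(res.phi.sum(axis=1) - 1).max() < 1e-10
        assert np.abs(res.theta.sum(axis=1) - 1).max() < 1e-10


class TestTopWords:
    def test_weights_non_increasing_and_ties_lexicographic(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 4, size=(10, 5))
        counts[counts.sum(axis=1) == 0, 0] = 1
        dtm = toy_dtm(counts, terms=["a", "b", "c", "d", "e"])
        res = LDA(dtm, K=2, alpha=0.3, beta=0.1).fit(n_iter=10, burn_in=5, seed=0)
        for ranked in res.top_words(10):
            weights = [w for _, w in ranked]
            assert weights == sorted(weights, reverse=True)
            assert len(ranked) == 5  # n > V returns all V terms
            for (t1, w1), (t2, w2) in zip(ranked, ranked[1:]):
                if w1 == w2:
                    assert t1 < t2


class TestCrossValidate:
    def test_default_grid(self):
        assert tuple(DEFAULT_K_GRID) == (10, 20, 30, 40, 50, 60, 100, 200)

    def test_single_fold_rejected(self):
        dtm = toy_dtm(np.ones((6, 4), dtype=int))
        with pytest.raises(ValueError):
            cross_validate_k(dtm, k_grid=[2], folds=1)

    def test_oversized_k_cells_invalid(self, small_corpus):
        from littopics.preprocess import clean_corpus, CleaningConfig
        records, _ = small_corpus
        dtm, _ = clean_corpus(records[:12], CleaningConfig(min_doc_frequency=2))
        result = cross_validate_k(
            dtm.fitted(), k_grid=[2, 500], folds=2, n_iter=10, burn_in=5, seed=0)
        assert np.isnan(result.fold_perplexity[1]).all()
        assert result.chosen_K == 2

    def test_selection_reports_argmin_and_elbow(self, small_corpus):
        from littopics.preprocess import clean_corpus, CleaningConfig
        records, _ = small_corpus
        dtm, _ = clean_corpus(records, CleaningConfig(min_doc_frequency=2))
        result = cross_validate_k(
            dtm.fitted(), k_grid=[2, 3, 5], folds=2, n_iter=30, burn_in=15, seed=0)
        assert result.argmin_K in result.k_grid
        assert result.elbow_K in result.k_grid
        assert result.chosen_K == result.elbow_K  # default rule
        assert (result.mean_perplexity > 0).all()
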