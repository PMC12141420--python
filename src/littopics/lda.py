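"""Latent Dirichlet Allocation by collapsed Gibbs sampling, with held-out
perplexity (document completion) and block cross-validated selection of the
number of topics.

Model
-----
Each document d mixes K topics with weights theta_d ~ Dirichlet(alpha);
each topic k is a distribution phi_k over the V vocabulary terms,
phi_k ~ Dirichlet(beta).  The collapsed sampler integrates theta and phi
out and resamples each token's topic assignment from

    p(z = k | rest)  ∝  (n_dk + alpha) * (n_kv + beta) / (n_k. + V*beta)

where the counts exclude the token being resampled.  Point estimates are
read off the final count state (optionally averaged over post-burn-in
samples):

    phi_kv   = (n_kv + beta)  / (n_k. + V*beta)
    theta_dk = (n_dk + alpha) / (n_d. + K*alpha)

Determinism: every document owns a random stream keyed by a stable hash of
its id, and documents are visited in sorted-id order, so a fixed seed gives
bit-identical output and permuting document order merely permutes theta
rows.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml
from numba import njit
from scipy.special import gammaln, logsumexp

from .preprocess import DocTermMatrix, Vocabulary


@dataclass
class LDAHyperparams:
    """Sampler settings.  alpha defaults to 50/K and beta to 0.1 (the
    common Gibbs-LDA conventions) when not given."""

    K: int
    alpha: float | None = None
    beta: float = 0.1
    n_iter: int = 2000
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.alpha is None:
            self.alpha = 50.0 / self.K
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")


def _doc_stream_seed(seed: int, doc_id: str) -> int:
    h = hashlib.blake2b(doc_id.encode("utf-8"), digest_size=8).digest()
    return (int.from_bytes(h, "big") ^ (seed * 0x9E3779B97F4A7C15)) % (2**63)


@njit(cache=True)
def _gibbs_sweep(z, w, d_of, n_dk, n_kv, n_k, alpha, beta, u, cum):
    K, V = n_kv.shape
    vbeta = V * beta
    for i in range(z.shape[0]):
        d = d_of[i]
        v = w[i]
        k_old = z[i]
        n_dk[d, k_old] -= 1
        n_kv[k_old, v] -= 1
        n_k[k_old] -= 1
        total = 0.0
        for k in range(K):
            p = (n_dk[d, k] + alpha) * (n_kv[k, v] + beta) / (n_k[k] + vbeta)
            total += p
            cum[k] = total
        r = u[i] * total
        k_new = 0
        while k_new < K - 1 and cum[k_new] < r:
            k_new += 1
        z[i] = k_new
        n_dk[d, k_new] += 1
        n_kv[k_new, v] += 1
        n_k[k_new] += 1


def collapsed_conditional(
    n_dk_d: np.ndarray, n_kv_v: np.ndarray, n_k: np.ndarray,
    alpha: float, beta: float, V: int,
) -> np.ndarray:
    """Collapsed-Gibbs full conditional p(z=k | rest) for one token, from
    counts that EXCLUDE that token.  Normalised to sum to 1."""
    p = (n_dk_d + alpha) * (n_kv_v + beta) / (n_k + V * beta)
    return p / p.sum()


def _expand_tokens(counts: sp.csr_matrix, row: int) -> np.ndarray:
    """Deterministic token list for one document: terms in vocabulary order,
    each repeated its count."""
    start, end = counts.indptr[row], counts.indptr[row + 1]
    return np.repeat(counts.indices[start:end], counts.data[start:end])


def _as_counts(dtm) -> tuple[sp.csr_matrix, list[str], list[str] | None]:
    if isinstance(dtm, DocTermMatrix):
        return dtm.counts, list(dtm.doc_ids), list(dtm.vocabulary.terms)
    counts = sp.csr_matrix(dtm)
    return counts, [f"doc{i:06d}" for i in range(counts.shape[0])], None


def log_joint(n_dk: np.ndarray, n_kv: np.ndarray, alpha: float, beta: float) -> float:
    """Collapsed joint log p(w, z) up to the multinomial token-order constant."""
    K, V = n_kv.shape
    D = n_dk.shape[0]
    n_k = n_kv.sum(axis=1)
    n_d = n_dk.sum(axis=1)
    lw = K * (gammaln(V * beta) - V * gammaln(beta))
    lw += gammaln(n_kv + beta).sum() - gammaln(n_k + V * beta).sum()
    ld = D * (gammaln(K * alpha) - K * gammaln(alpha))
    ld += gammaln(n_dk + alpha).sum() - gammaln(n_d + K * alpha).sum()
    return float(lw + ld)


class LDA:
    """Collapsed-Gibbs LDA model bound to a document-term matrix.

    Parameters
    ----------
    dtm : DocTermMatrix or sparse/dense counts
        Rows with zero tokens are rejected; filter with
        ``DocTermMatrix.fitted()`` first.
    K, alpha, beta : topic number and symmetric Dirichlet concentrations.
    """

    def __init__(self, dtm, K: int, alpha: float | None = None, beta: float = 0.1):
        counts, doc_ids, terms = _as_counts(dtm)
        doc_lengths = np.asarray(counts.sum(axis=1)).ravel()
        if (doc_lengths == 0).any():
            raise ValueError(
                "document-term matrix contains all-zero rows; "
                "use DocTermMatrix.fitted() to drop them before fitting")
        self.counts = counts
        self.doc_ids = doc_ids
        self.terms = terms
        self.hyper = LDAHyperparams(K=K, alpha=alpha, beta=beta)
        if counts.shape[1] < K:
            warnings.warn(f"V={counts.shape[1]} < K={K}; topics cannot all be distinct")

    def fit(
        self,
        n_iter: int = 2000,
        burn_in: int = 1000,
        seed: int = 0,
        average_every: int | None = None,
        loglik_every: int = 1,
    ) -> "LDAResults":
        """Run the sampler.

        ``average_every=m`` averages phi/theta over every m-th post-burn-in
        sweep instead of reading them off the final state.
        """
        hyper = LDAHyperparams(
            K=self.hyper.K, alpha=self.hyper.alpha, beta=self.hyper.beta,
            n_iter=n_iter, burn_in=burn_in, seed=seed)
        K = hyper.K
        alpha, beta = float(hyper.alpha), float(hyper.beta)
        counts = self.counts
        D, V = counts.shape

        order = np.argsort(np.array(self.doc_ids, dtype=object), kind="stable")
        gens = [
            np.random.Generator(np.random.PCG64(_doc_stream_seed(seed, self.doc_ids[d])))
            for d in order
        ]
        tok_w = np.concatenate([_expand_tokens(counts, d) for d in order]).astype(np.int32)
        doc_len = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)[order]
        tok_d = np.repeat(order.astype(np.int32), doc_len)
        N = tok_w.shape[0]

        # init from the per-document streams
        u0 = np.concatenate([g.random(n) for g, n in zip(gens, doc_len)])
        z = np.minimum((u0 * K).astype(np.int32), K - 1)
        n_dk = np.zeros((D, K), dtype=np.int64)
        n_kv = np.zeros((K, V), dtype=np.int64)
        np.add.at(n_dk, (tok_d, z), 1)
        np.add.at(n_kv, (z, tok_w), 1)
        n_k = n_kv.sum(axis=1)
        cum = np.empty(K, dtype=np.float64)

        trace: list[float] = []
        phi_acc = np.zeros((K, V))
        theta_acc = np.zeros((D, K))
        n_acc = 0
        for sweep in range(n_iter):
            u = np.concatenate([g.random(n) for g, n in zip(gens, doc_len)])
            _gibbs_sweep(z, tok_w, tok_d, n_dk, n_kv, n_k, alpha, beta, u, cum)
            if loglik_every and (sweep + 1) % loglik_every == 0:
                trace.append(log_joint(n_dk, n_kv, alpha, beta))
            if (average_every and sweep >= burn_in
                    and (sweep - burn_in) % average_every == 0):
                phi_acc += (n_kv + beta) / (n_k + V * beta)[:, None]
                theta_acc += (n_dk + alpha) / (n_dk.sum(axis=1) + K * alpha)[:, None]
                n_acc += 1

        if n_acc:
            phi = phi_acc / n_acc
            theta = theta_acc / n_acc
        else:
            phi = (n_kv + beta) / (n_k + V * beta)[:, None]
            theta = (n_dk + alpha) / (n_dk.sum(axis=1) + K * alpha)[:, None]
        return LDAResults(
            model=self, hyper=hyper, phi=phi, theta=theta,
            z=z, token_word=tok_w, token_doc=tok_d,
            n_kv=n_kv, n_dk=n_dk,
            loglik_trace=np.array(trace), loglik_every=loglik_every or 0)


@dataclass
class LDAResults:
    """Fitted LDA state: topic-word distribution ``phi`` (K x V, the
    per-topic word weights), document-topic distribution ``theta`` (D x K,
    the per-article topic weights), token assignments and count matrices."""

    model: LDA
    hyper: LDAHyperparams
    phi: np.ndarray
    theta: np.ndarray
    z: np.ndarray
    token_word: np.ndarray
    token_doc: np.ndarray
    n_kv: np.ndarray
    n_dk: np.ndarray
    loglik_trace: np.ndarray
    loglik_every: int = 1

    @property
    def K(self) -> int:
        return self.hyper.K

    @property
    def doc_ids(self) -> list[str]:
        return self.model.doc_ids

    @property
    def terms(self) -> list[str] | None:
        return self.model.terms

    def top_words(self, n: int = 20) -> list[list[tuple[str, float]]]:
        """Per topic, the n highest-weight terms (phi descending, ties
        broken lexicographically).  n beyond V returns all V terms."""
        terms = self.terms or [f"term{j}" for j in range(self.phi.shape[1])]
        out = []
        for k in range(self.K):
            ranked = sorted(zip(terms, self.phi[k]), key=lambda tw: (-tw[1], tw[0]))
            out.append([(t, float(wt)) for t, wt in ranked[:n]])
        return out

    def perplexity(self, heldout, seed: int = 0, n_foldin: int = 50) -> float:
        return perplexity(self.phi, heldout, alpha=float(self.hyper.alpha),
                          terms=self.terms, seed=seed, n_foldin=n_foldin)

    def summary(self, n_words: int = 10) -> str:
        lines = [
            f"LDA (collapsed Gibbs)  K={self.K}  alpha={self.hyper.alpha:.4g}  "
            f"beta={self.hyper.beta:.4g}",
            f"documents: {self.theta.shape[0]}  vocabulary: {self.phi.shape[1]}  "
            f"tokens: {self.z.shape[0]}",
            f"sweeps: {self.hyper.n_iter} (burn-in {self.hyper.burn_in}), "
            f"seed {self.hyper.seed}",
        ]
        if self.loglik_trace.size:
            lines.append(f"final joint log-likelihood: {self.loglik_trace[-1]:.2f}")
        for k, words in enumerate(self.top_words(n_words)):
            lines.append(f"topic {k:3d}: " + ", ".join(t for t, _ in words))
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(outdir / "phi.mtx", np.asarray(self.phi))
        scipy.io.mmwrite(outdir / "theta.mtx", np.asarray(self.theta))
        np.savez_compressed(
            outdir / "state.npz", z=self.z, token_word=self.token_word,
            token_doc=self.token_doc, n_kv=self.n_kv, n_dk=self.n_dk,
            loglik_trace=self.loglik_trace)
        meta = {
            "K": self.K, "alpha": float(self.hyper.alpha),
            "beta": float(self.hyper.beta), "n_iter": self.hyper.n_iter,
            "burn_in": self.hyper.burn_in, "seed": self.hyper.seed,
            "loglik_every": self.loglik_every,
            "doc_ids": self.doc_ids, "terms": self.terms,
        }
        with open(outdir / "model.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh)


def perplexity(
    phi: np.ndarray,
    heldout,
    alpha: float,
    terms: Sequence[str] | None = None,
    seed: int = 0,
    n_foldin: int = 50,
) -> float:
    """Document-completion held-out perplexity.

    Each held-out document's tokens (vocabulary-order expansion) are split
    alternately into a fold-in half and an evaluation half.  The fold-in
    half estimates theta_d by short Gibbs runs against fixed phi; the
    evaluation half is scored under sum_k theta_dk phi_kv.  Returns
    exp(-mean per-token log-likelihood) over all evaluation tokens.

    Held-out terms absent from the model vocabulary are excluded with a
    warning.
    """
    phi = np.asarray(phi, dtype=np.float64)
    K, V = phi.shape
    counts, doc_ids, ho_terms = _as_counts(heldout)
    if ho_terms is not None and terms is not None and list(ho_terms) != list(terms):
        counts, n_oov = _align_vocab(counts, ho_terms, list(terms))
        if n_oov:
            warnings.warn(f"{n_oov} held-out tokens outside model vocabulary excluded")
    if counts.shape[1] != V:
        raise ValueError("held-out vocabulary incompatible with model phi")

    log_phi = np.log(phi)
    total_lp = 0.0
    n_eval = 0
    for row in range(counts.shape[0]):
        toks = _expand_tokens(counts, row)
        if toks.size == 0:
            continue
        foldin, evaltoks = toks[0::2], toks[1::2]
        gen = np.random.Generator(np.random.PCG64(
            _doc_stream_seed(seed, "heldout:" + doc_ids[row])))
        ndk = np.zeros(K)
        if foldin.size:
            p0 = phi[:, foldin].T  # init from phi alone
            p0 = p0 / p0.sum(axis=1, keepdims=True)
            u = gen.random(foldin.size)
            zf = np.minimum((p0.cumsum(axis=1) < u[:, None]).sum(axis=1), K - 1)
            np.add.at(ndk, zf, 1)
            for _ in range(n_foldin):
                for i, v in enumerate(foldin):
                    ndk[zf[i]] -= 1
                    p = (ndk + alpha) * phi[:, v]
                    p /= p.sum()
                    zk = min(int((p.cumsum() < gen.random()).sum()), K - 1)
                    zf[i] = zk
                    ndk[zk] += 1
        theta_d = (ndk + alpha) / (ndk.sum() + K * alpha)
        if evaltoks.size:
            lp = logsumexp(np.log(theta_d)[:, None] + log_phi[:, evaltoks], axis=0)
            total_lp += lp.sum()
            n_eval += evaltoks.size
    if n_eval == 0:
        raise ValueError("no evaluation tokens in held-out set")
    return float(np.exp(-total_lp / n_eval))


def _align_vocab(counts: sp.csr_matrix, ho_terms: list[str], terms: list[str]):
    idx = {t: j for j, t in enumerate(terms)}
    cols = np.array([idx.get(t, -1) for t in ho_terms])
    keep = cols >= 0
    n_oov = int(counts[:, ~keep].sum())
    kept_counts = counts[:, keep].tocoo()
    colmap = cols[keep]
    aligned_rows = sp.csr_matrix(
        (kept_counts.data, (kept_counts.row, colmap[kept_counts.col])),
        shape=(counts.shape[0], len(terms)))
    return aligned_rows, n_oov


@dataclass
class CVResult:
    """Cross-validated perplexity over a grid of topic numbers."""

    k_grid: list[int]
    fold_perplexity: np.ndarray  # len(k_grid) x folds, NaN = invalid cell
    mean_perplexity: np.ndarray
    argmin_K: int
    elbow_K: int
    selection_rule: str
    chosen_K: int

    def summary(self) -> str:
        lines = ["block cross-validated perplexity",
                 f"{'K':>6} {'mean perplexity':>18}"]
        for k, m in zip(self.k_grid, self.mean_perplexity):
            mark = " <- chosen" if k == self.chosen_K else ""
            lines.append(f"{k:>6} {m:>18.3f}{mark}")
        lines.append(f"argmin K = {self.argmin_K}; elbow K = {self.elbow_K}; "
                     f"rule = {self.selection_rule}")
        return "\n".join(lines)


DEFAULT_K_GRID = (10, 20, 30, 40, 50, 60, 100, 200)


def cross_validate_k(
    dtm,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    folds: int = 5,
    alpha: float | None = None,
    beta: float = 0.1,
    n_iter: int = 500,
    burn_in: int = 250,
    seed: int = 0,
    elbow_tol: float = 0.05,
    selection_rule: str = "elbow",
    n_foldin: int = 50,
) -> CVResult:
    """Document-level block cross-validation of held-out perplexity.

    Documents are shuffled once (seeded) then split into ``folds``
    contiguous blocks; for each candidate K and each fold the model is fit
    on the remaining blocks and scored on the held-out block by document
    completion.  Cells where K reaches the training vocabulary or document
    count are marked invalid (NaN) and excluded from selection.

    The elbow is the last K before the relative improvement of mean
    perplexity first drops below ``elbow_tol``; the argmin is also
    reported, and ``selection_rule`` ("elbow" or "argmin") names which one
    ``chosen_K`` follows.
    """
    if folds < 2:
        raise ValueError("need folds >= 2")
    if selection_rule not in ("elbow", "argmin"):
        raise ValueError("selection_rule must be 'elbow' or 'argmin'")
    counts, doc_ids, terms = _as_counts(dtm)
    D = counts.shape[0]
    if D < folds:
        raise ValueError("fewer documents than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(D)
    blocks = np.array_split(perm, folds)

    k_grid = sorted(int(k) for k in k_grid)
    perp = np.full((len(k_grid), folds), np.nan)
    for f, test_idx in enumerate(blocks):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        train_counts = counts[train_idx]
        used_cols = np.asarray(train_counts.sum(axis=0)).ravel() > 0
        train_V = int(used_cols.sum())
        sub = DocTermMatrix(
            counts=train_counts,
            doc_ids=[doc_ids[i] for i in train_idx],
            vocabulary=_trivial_vocab(terms, counts.shape[1]),
        )
        test = counts[test_idx]
        test_ids = [doc_ids[i] for i in test_idx]
        for ki, k in enumerate(k_grid):
            if k >= train_V or k >= len(train_idx):
                continue  # invalid cell
            res = LDA(sub, K=k, alpha=alpha, beta=beta).fit(
                n_iter=n_iter, burn_in=burn_in, seed=seed, loglik_every=0)
            test_dtm = DocTermMatrix(
                counts=test, doc_ids=test_ids,
                vocabulary=_trivial_vocab(terms, counts.shape[1]))
            perp[ki, f] = perplexity(
                res.phi, test_dtm, alpha=float(res.hyper.alpha),
                terms=terms, seed=seed, n_foldin=n_foldin)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid rows
        mean = np.nanmean(perp, axis=1)
    valid = ~np.isnan(mean)
    if not valid.any():
        raise RuntimeError("no valid (K, fold) cells")
    valid_ks = [k for k, v in zip(k_grid, valid) if v]
    valid_means = mean[valid]
    argmin_K = valid_ks[int(np.argmin(valid_means))]
    elbow_K = valid_ks[-1]
    for i in range(1, len(valid_ks)):
        rel_impr = (valid_means[i - 1] - valid_means[i]) / valid_means[i - 1]
        if rel_impr < elbow_tol:
            elbow_K = valid_ks[i - 1]
            break
    chosen = elbow_K if selection_rule == "elbow" else argmin_K
    return CVResult(
        k_grid=list(k_grid), fold_perplexity=perp, mean_perplexity=mean,
        argmin_K=argmin_K, elbow_K=elbow_K,
        selection_rule=selection_rule, chosen_K=chosen)


def _trivial_vocab(terms: list[str] | None, V: int) -> Vocabulary:
    ts = list(terms) if terms is not None else [f"t{j:06d}" for j in range(V)]
    return Vocabulary(ts, np.ones(len(ts), dtype=int))
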