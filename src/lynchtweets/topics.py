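"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model: each document d draws a topic mixture theta_d ~ Dirichlet(alpha),
each topic k a word distribution phi_k ~ Dirichlet(beta); every token first
draws a topic z from theta_d, then a word from phi_z. Inference integrates
theta and phi out and resamples per-token topic indicators z with the
collapsed conditional

    p(z_i = k | z_-i, w) ∝ (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta).

Point estimates are posterior means from the final sweep's counts.

Also provided: three diagnostics for choosing the number of topics K
(symmetric KL between matrix-factor distributions, lower better; mean
inter-topic cosine, lower better; mean inter-topic Jensen–Shannon
divergence, higher better), probability-cutoff topic assignment, and
top-word export for word clouds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment


class Corpus:
    """Vocabulary plus flattened token stream of a document collection."""

    def __init__(self, documents: Sequence[Sequence[str]], doc_ids=None):
        self.doc_ids = list(doc_ids) if doc_ids is not None else [
            str(i) for i in range(len(documents))
        ]
        if len(self.doc_ids) != len(documents):
            raise ValueError("doc_ids length must match documents")
        vocab: dict[str, int] = {}
        doc_of, word_of = [], []
        lengths = np.zeros(len(documents), dtype=np.int64)
        for d, doc in enumerate(documents):
            for tok in doc:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
                doc_of.append(d)
                word_of.append(vocab[tok])
            lengths[d] = len(doc)
        self.vocab = list(vocab)
        self.doc_of = np.asarray(doc_of, dtype=np.int64)
        self.word_of = np.asarray(word_of, dtype=np.int64)
        self.doc_lengths = lengths

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)

    @property
    def n_words(self) -> int:
        return len(self.vocab)

    @property
    def n_tokens(self) -> int:
        return int(self.doc_of.shape[0])


@njit(cache=True)
def _gibbs_kernel(doc_of, word_of, n_docs, K, V, alpha, beta, n_sweeps, seed, trace):
    """Run collapsed Gibbs sweeps; returns (z, ndk, nkw, nk).

    All randomness (initial assignment and resampling) flows from one
    seeded stream. When ``trace`` is nonempty it receives the per-topic
    token counts nk after every sweep.
    """
    np.random.seed(seed)
    n_tokens = doc_of.shape[0]
    z = np.empty(n_tokens, dtype=np.int64)
    ndk = np.zeros((n_docs, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    for i in range(n_tokens):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_of[i], k] += 1
        nkw[k, word_of[i]] += 1
        nk[k] += 1
    cum = np.empty(K, dtype=np.float64)
    vb = V * beta
    for s in range(n_sweeps):
        for i in range(n_tokens):
            d = doc_of[i]
            w = word_of[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vb)
                cum[kk] = total
            u = np.random.random() * total
            knew = 0
            while cum[knew] < u and knew < K - 1:
                knew += 1
            z[i] = knew
            ndk[d, knew] += 1
            nkw[knew, w] += 1
            nk[knew] += 1
        if trace.shape[0] > 0:
            for kk in range(K):
                trace[s, kk] = nk[kk]
    return z, ndk, nkw, nk


@dataclass
class TopicModel:
    """Fitted LDA model: posterior-mean phi/theta plus final sampler state."""

    K: int
    alpha: float
    beta: float
    phi: np.ndarray        # K x V topic-word probabilities
    theta: np.ndarray      # D x K document-topic probabilities
    assignments: np.ndarray  # per-token topic indices (final sweep)
    vocab: list[str]
    doc_ids: list[str] = field(default_factory=list)
    nk_trace: np.ndarray | None = None


def fit_lda(
    corpus: Corpus,
    K: int,
    alpha: float | None = None,
    beta: float = 0.1,
    n_sweeps: int = 1000,
    seed: int = 0,
    keep_trace: bool = False,
) -> TopicModel:
    """Fit LDA with collapsed Gibbs sampling; deterministic given *seed*.

    Defaults alpha = 50/K and beta = 0.1 (the classic Griffiths–Steyvers
    choice). Estimates are Dirichlet-smoothed posterior means from the
    final sweep's counts, not averages over samples.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if corpus.n_tokens == 0:
        raise ValueError("corpus has no tokens")
    if K > corpus.n_tokens:
        raise ValueError(f"K={K} exceeds total token count {corpus.n_tokens}")
    if alpha is None:
        alpha = 50.0 / K
    V = corpus.n_words
    trace = np.zeros((n_sweeps if keep_trace else 0, K), dtype=np.int64)
    z, ndk, nkw, nk = _gibbs_kernel(
        corpus.doc_of, corpus.word_of, corpus.n_docs, K, V,
        float(alpha), float(beta), n_sweeps, seed, trace,
    )
    phi = (nkw + beta) / (nk[:, None] + V * beta)
    theta = (ndk + alpha) / (corpus.doc_lengths[:, None] + K * alpha)
    return TopicModel(
        K=K, alpha=float(alpha), beta=float(beta), phi=phi, theta=theta,
        assignments=z, vocab=list(corpus.vocab), doc_ids=list(corpus.doc_ids),
        nk_trace=trace if keep_trace else None,
    )


def _sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, None)
    q = np.clip(q, eps, None)
    return float(np.sum((p - q) * np.log(p / q)))


def arun_metric(model: TopicModel, doc_lengths: np.ndarray) -> float:
    """Symmetric KL between the two K-length factor distributions.

    Compares the normalized singular values of the topic-word matrix with
    the document-length-weighted, normalized topic proportions from the
    document-topic matrix. Lower values indicate a better-conditioned
    factorization; the curve tends to rise away from an adequate K.
    """
    if model.K == 0:
        raise ValueError("model has no topics")
    sv = np.linalg.svd(model.phi, compute_uv=False)
    p = sv / sv.sum()
    lengths = np.asarray(doc_lengths, dtype=float)
    if lengths.shape[0] != model.theta.shape[0]:
        raise ValueError("doc_lengths must align with theta rows")
    q = lengths @ model.theta
    q = q / q.sum()
    return _sym_kl(p, q)


def cao_metric(model: TopicModel) -> float:
    """Mean pairwise cosine similarity between topic-word rows (lower better)."""
    if model.K < 2:
        raise ValueError("cao_metric requires K >= 2")
    phi = model.phi
    norms = np.linalg.norm(phi, axis=1)
    sims = (phi @ phi.T) / np.outer(norms, norms)
    iu = np.triu_indices(model.K, k=1)
    return float(sims[iu].mean())


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    eps = 1e-12
    m = 0.5 * (p + q)
    p = np.clip(p, eps, None)
    q = np.clip(q, eps, None)
    m = np.clip(m, eps, None)
    return float(
        0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m))
    )


def deveaud_metric(model: TopicModel) -> float:
    """Mean pairwise Jensen–Shannon divergence (natural log) between topics.

    Higher values mean more mutually distinct topics; bounded by ln 2.
    """
    if model.K < 2:
        raise ValueError("deveaud_metric requires K >= 2")
    vals = [
        _jsd(model.phi[i], model.phi[j])
        for i, j in itertools.combinations(range(model.K), 2)
    ]
    return float(np.mean(vals))


def select_k(
    corpus: Corpus,
    k_grid: Sequence[int],
    alpha: float | None = None,
    beta: float = 0.1,
    n_sweeps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one model per candidate K and tabulate the three diagnostics.

    Each K is fitted from scratch with the seed offset by K, so the grid
    points are mutually independent chains.
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    if any(k < 2 for k in k_grid):
        raise ValueError("all candidate K must be >= 2")
    rows = []
    for k in k_grid:
        model = fit_lda(corpus, k, alpha=alpha, beta=beta,
                        n_sweeps=n_sweeps, seed=seed + k)
        rows.append({
            "K": k,
            "arun": arun_metric(model, corpus.doc_lengths),
            "cao": cao_metric(model),
            "deveaud": deveaud_metric(model),
        })
    return pd.DataFrame(rows).set_index("K")


@dataclass
class TopicAssignment:
    """Cutoff-thresholded topic attribution for one tweet.

    ``selected`` holds every (topic, probability) with probability at or
    above the cutoff, sorted by descending probability; ``primary`` is the
    highest-probability topic (lowest index on exact ties) or None when no
    topic clears the cutoff.
    """

    tweet_id: str
    topic_probs: np.ndarray
    selected: list[tuple[int, float]]
    primary: int | None
    label: str | None = None


def assign_topics(
    model: TopicModel,
    cutoff: float = 0.1,
    label_map: Mapping[int, str] | None = None,
) -> list[TopicAssignment]:
    """Threshold each document's topic probabilities at *cutoff*.

    Documents where no topic reaches the cutoff get an empty selection and
    no primary topic, mirroring tweets left unassigned in practice.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    out = []
    for d, row in enumerate(model.theta):
        idx = np.flatnonzero(row >= cutoff)
        # descending probability; ties broken by lower topic index
        order = sorted(idx, key=lambda k: (-row[k], k))
        selected = [(int(k), float(row[k])) for k in order]
        primary = selected[0][0] if selected else None
        label = None
        if primary is not None and label_map:
            label = label_map.get(primary)
        tid = model.doc_ids[d] if model.doc_ids else str(d)
        out.append(TopicAssignment(tid, row, selected, primary, label))
    return out


def top_words(model: TopicModel, topic: int, n: int = 20) -> list[tuple[str, float]]:
    """The *n* highest-probability words of a topic, descending.

    Exact probability ties are broken by lexicographic word order so the
    export is deterministic.
    """
    if not 0 <= topic < model.K:
        raise ValueError(f"topic index {topic} out of range for K={model.K}")
    if n < 1:
        raise ValueError("n must be >= 1")
    row = model.phi[topic]
    pairs = sorted(zip(model.vocab, row), key=lambda wp: (-wp[1], wp[0]))
    return [(w, float(p)) for w, p in pairs[:n]]


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally pair estimated and true topics by total-variation distance.

    Returns (permutation mapping true index -> estimated index, mean matched
    TV distance). Uses the Hungarian assignment on the pairwise TV matrix.
    """
    K = phi_true.shape[0]
    cost = np.empty((K, phi_est.shape[0]))
    for i in range(K):
        cost[i] = 0.5 * np.abs(phi_est - phi_true[i]).sum(axis=1)
    rows, cols = linear_sum_assignment(cost)
    return cols, float(cost[rows, cols].mean())
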