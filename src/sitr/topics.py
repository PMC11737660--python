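"""Latent Dirichlet Allocation by collapsed Gibbs sampling.

Each training subset gets its own topic model: K latent topics, each a
distribution over the subset vocabulary, with per-document topic mixtures.
Collapsed Gibbs sampling integrates out the Dirichlet parameters and
resamples the topic assignment of every token conditional on all others:

    p(z_i = k | z_-i, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + Vβ)

Point estimates are taken from the final post-burn-in count state by
default (deterministic and alignment-stable for codebook construction);
sample averaging over post-burn-in sweeps is available behind a flag.

A topic's *proportion estimate* — its importance within the subset — is the
mean of its document-mixture column, expressed as an integer percent
(rounded half-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda fn: fn

__all__ = [
    "TopicModel",
    "TopicSpec",
    "fit_lda",
    "proportion_estimates",
    "key_tokens",
    "topic_coherence",
]


@njit(cache=True)
def _gibbs(words, doc_of, D, V, K, alpha, beta, n_iter, burn_in, seed, average):
    np.random.seed(seed)
    N = words.shape[0]
    z = np.empty(N, dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.float64)
    n_kw = np.zeros((K, V), dtype=np.float64)
    n_k = np.zeros(K, dtype=np.float64)
    for i in range(N):
        k = np.random.randint(0, K)
        z[i] = k
        n_dk[doc_of[i], k] += 1.0
        n_kw[k, words[i]] += 1.0
        n_k[k] += 1.0
    phi_acc = np.zeros((K, V), dtype=np.float64)
    theta_acc = np.zeros((D, K), dtype=np.float64)
    n_samples = 0
    probs = np.empty(K, dtype=np.float64)
    vbeta = V * beta
    for it in range(n_iter):
        for i in range(N):
            d = doc_of[i]
            w = words[i]
            k = z[i]
            n_dk[d, k] -= 1.0
            n_kw[k, w] -= 1.0
            n_k[k] -= 1.0
            total = 0.0
            for kk in range(K):
                p = (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + vbeta)
                total += p
                probs[kk] = total
            u = np.random.random() * total
            k_new = 0
            while probs[k_new] < u and k_new < K - 1:
                k_new += 1
            z[i] = k_new
            n_dk[d, k_new] += 1.0
            n_kw[k_new, w] += 1.0
            n_k[k_new] += 1.0
        if average and it >= burn_in:
            n_samples += 1
            for kk in range(K):
                for w in range(V):
                    phi_acc[kk, w] += (n_kw[kk, w] + beta) / (n_k[kk] + vbeta)
            for d in range(D):
                nd = 0.0
                for kk in range(K):
                    nd += n_dk[d, kk]
                for kk in range(K):
                    theta_acc[d, kk] += (n_dk[d, kk] + alpha) / (nd + K * alpha)
    return z, n_dk, n_kw, n_k, phi_acc, theta_acc, n_samples


def proportion_estimates(doc_mixtures: np.ndarray) -> list[int]:
    """Integer-percent topic importances: column means of the document
    mixtures, times 100, rounded half-up.  Values sum to 100 up to a
    rounding slack of ceil(K/2)."""
    means = np.asarray(doc_mixtures, dtype=float).mean(axis=0)
    return [int(np.floor(m * 100.0 + 0.5)) for m in means]


@dataclass(frozen=True)
class TopicSpec:
    """Metadata for one topic: human-assigned title and key tokens."""

    topic_index: int
    title: str
    key_tokens: tuple[str, ...]
    proportion_estimate: int


@dataclass
class TopicModel:
    """A fitted per-subset LDA model.

    ``topic_token_weights`` is K x V (rows sum to 1); ``doc_mixtures`` is
    D x K (rows sum to 1); ``proportion_estimates`` are integer percents.
    """

    K: int
    vocabulary: list[str]
    topic_token_weights: np.ndarray
    doc_mixtures: np.ndarray
    proportion_estimates: list[int]
    assignments: np.ndarray
    alpha: float
    beta: float
    n_iter: int
    burn_in: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "vocabulary": list(self.vocabulary),
            "topic_token_weights": self.topic_token_weights.tolist(),
            "doc_mixtures": self.doc_mixtures.tolist(),
            "proportion_estimates": list(self.proportion_estimates),
            "assignments": self.assignments.tolist(),
            "meta": {
                "alpha": self.alpha,
                "beta": self.beta,
                "n_iter": self.n_iter,
                "burn_in": self.burn_in,
                "seed": self.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TopicModel":
        meta = d["meta"]
        return cls(
            K=d["K"],
            vocabulary=list(d["vocabulary"]),
            topic_token_weights=np.asarray(d["topic_token_weights"], dtype=float),
            doc_mixtures=np.asarray(d["doc_mixtures"], dtype=float),
            proportion_estimates=list(d["proportion_estimates"]),
            assignments=np.asarray(d["assignments"], dtype=np.int64),
            alpha=meta["alpha"],
            beta=meta["beta"],
            n_iter=meta["n_iter"],
            burn_in=meta["burn_in"],
            seed=meta["seed"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TopicModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_lda(
    corpus: Sequence[Sequence[str]],
    K: int = 10,
    alpha: float = 0.1,
    beta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    average_samples: bool = False,
) -> TopicModel:
    """Fit a K-topic LDA model to tokenized documents by collapsed Gibbs.

    Deterministic for a fixed seed.  ``average_samples=True`` averages the
    smoothed estimates over every post-burn-in sweep instead of using the
    final count state.

    Raises ``ValueError`` on an empty corpus or empty vocabulary.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not (n_iter >= burn_in >= 0):
        raise ValueError("need n_iter >= burn_in >= 0")
    docs = [list(d) for d in corpus]
    if not docs:
        raise ValueError("empty corpus")
    vocabulary = sorted({t for d in docs for t in d})
    if not vocabulary:
        raise ValueError("empty vocabulary (all documents are empty)")
    vindex = {t: i for i, t in enumerate(vocabulary)}
    words = np.array([vindex[t] for d in docs for t in d], dtype=np.int64)
    doc_of = np.array(
        [di for di, d in enumerate(docs) for _ in d], dtype=np.int64
    )
    D, V = len(docs), len(vocabulary)

    z, n_dk, n_kw, n_k, phi_acc, theta_acc, n_samples = _gibbs(
        words, doc_of, D, V, K, float(alpha), float(beta),
        int(n_iter), int(burn_in), int(seed) & 0x7FFFFFFF, bool(average_samples),
    )

    if average_samples and n_samples > 0:
        phi = phi_acc / n_samples
        theta = theta_acc / n_samples
    else:
        phi = (n_kw + beta) / (n_k[:, None] + V * beta)
        nd = n_dk.sum(axis=1, keepdims=True)
        theta = (n_dk + alpha) / (nd + K * alpha)
    phi /= phi.sum(axis=1, keepdims=True)
    theta /= theta.sum(axis=1, keepdims=True)

    return TopicModel(
        K=K,
        vocabulary=vocabulary,
        topic_token_weights=phi,
        doc_mixtures=theta,
        proportion_estimates=proportion_estimates(theta),
        assignments=z,
        alpha=alpha,
        beta=beta,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
    )


def key_tokens(
    model: TopicModel, topic: int, n: int = 20, min_weight: float = 0.0
) -> list[str]:
    """The n highest-weight tokens of a topic with weight >= ``min_weight``,
    descending by weight, ties broken lexicographically."""
    if not (0 <= topic < model.K):
        raise ValueError(f"topic {topic} out of range for K={model.K}")
    w = model.topic_token_weights[topic]
    widx = {tok: w[i] for i, tok in enumerate(model.vocabulary)}
    ranked = sorted(
        (tok for tok in model.vocabulary if widx[tok] >= min_weight),
        key=lambda tok: (-widx[tok], tok),
    )
    return ranked[:n]


def topic_coherence(
    model: TopicModel, corpus: Sequence[Sequence[str]], top_n: int = 10
) -> list[float]:
    """UMass document-co-occurrence coherence per topic (higher = better).

    For a topic's top tokens w_1..w_T (by weight), the score sums
    log((D(w_t, w_l) + 1) / D(w_l)) over all ordered pairs l < t, where D
    counts documents containing the token(s).  A model-selection diagnostic
    only; it plays no role in assessment.
    """
    doc_sets = [frozenset(d) for d in corpus]
    scores = []
    for k in range(model.K):
        top = key_tokens(model, k, n=top_n)
        s = 0.0
        for t in range(1, len(top)):
            for l in range(t):
                d_l = sum(1 for ds in doc_sets if top[l] in ds)
                if d_l == 0:
                    continue
                d_tl = sum(1 for ds in doc_sets if top[l] in ds and top[t] in ds)
                s += float(np.log((d_tl + 1.0) / d_l))
        scores.append(s)
    return scores
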