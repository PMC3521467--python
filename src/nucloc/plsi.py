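"""Probabilistic latent semantic indexing (aspect model) from scratch.

The joint weight of word ``w`` in document ``d`` is modelled through latent
topics: ``P(w, d) = P(d) * sum_t P(w|t) P(t|d)``.  Parameters are fitted by
expectation-maximization on a (possibly real-valued) word-document weight
matrix; unseen documents are projected onto the trained topics by a
folding-in EM that keeps ``P(w|t)`` frozen.

Implementation notes
--------------------
* E-step responsibilities ``P(t|d,w) ∝ (P(w|t) P(t|d))^beta`` — ``beta=1``
  is plain EM; the tempering exponent is exposed but not used by default.
* ``P(d)`` is the document's share of total corpus weight (its maximum-
  likelihood value, which EM never moves).
* Probabilities are clamped at 1e-12 inside logarithms so structural zeros
  yield a large negative, not infinite, log-likelihood.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

PROB_FLOOR = 1e-12
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-6
FOLD_IN_MAX_ITER = 50


@dataclass(frozen=True)
class Corpus:
    """Weighted word-document co-occurrence data.

    ``counts[i, j]`` is the nonnegative weight of ``vocabulary[j]`` in
    ``documents[i]``; weights need not be integers.
    """

    documents: list[str]
    vocabulary: list[str]
    counts: np.ndarray  # shape (n_docs, n_words)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.documents), len(self.vocabulary)):
            raise ValueError(
                f"counts shape {counts.shape} != (docs={len(self.documents)}, words={len(self.vocabulary)})"
            )
        if counts.size == 0:
            raise ValueError("empty corpus")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("corpus weights must be finite and nonnegative")
        if np.any(counts.sum(axis=1) <= 0):
            empty = [self.documents[i] for i in np.flatnonzero(counts.sum(axis=1) <= 0)]
            raise ValueError(f"documents with no positive weight: {empty}")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_feature_vectors(cls, vectors, prune_empty_words: bool = True) -> "Corpus":
        """Build a corpus from :class:`~nucloc.features.FeatureVector` objects."""
        from .features import feature_matrix, word_order

        if not vectors:
            raise ValueError("empty corpus")
        order = word_order(vectors[0].d_max)
        mat = feature_matrix(vectors, order)
        vocab = list(order)
        if prune_empty_words:
            keep = np.flatnonzero(mat.sum(axis=0) > 0)
            mat = mat[:, keep]
            vocab = [vocab[j] for j in keep]
        return cls([fv.protein_id for fv in vectors], vocab, mat)


@dataclass
class PLSIModel:
    """Fitted aspect model with K topics."""

    K: int
    documents: list[str]
    vocabulary: list[str]
    word_given_topic: np.ndarray  # (n_words, K), columns sum to 1
    topic_given_doc: np.ndarray  # (K, n_docs), columns sum to 1
    doc_prior: np.ndarray  # (n_docs,)
    log_likelihood_trace: list[float] = field(default_factory=list)
    seed: int = 0
    beta: float = 1.0

    def topic_matrix(self) -> np.ndarray:
        """Per-document topic weights as an (n_docs, K) matrix."""
        return self.topic_given_doc.T.copy()

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "K": self.K,
            "documents": self.documents,
            "vocabulary": self.vocabulary,
            "word_given_topic": self.word_given_topic.tolist(),
            "topic_given_doc": self.topic_given_doc.tolist(),
            "doc_prior": self.doc_prior.tolist(),
            "log_likelihood_trace": self.log_likelihood_trace,
            "seed": self.seed,
            "beta": self.beta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PLSIModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            K=payload["K"],
            documents=payload["documents"],
            vocabulary=payload["vocabulary"],
            word_given_topic=np.array(payload["word_given_topic"], dtype=float),
            topic_given_doc=np.array(payload["topic_given_doc"], dtype=float),
            doc_prior=np.array(payload["doc_prior"], dtype=float),
            log_likelihood_trace=list(payload["log_likelihood_trace"]),
            seed=payload["seed"],
            beta=payload["beta"],
        )


@dataclass(frozen=True)
class FoldInResult:
    """Topic distribution of an unseen document; ``in_vocabulary`` is False
    when the document shared no words with the training vocabulary and the
    returned distribution is the uninformative uniform one."""

    distribution: np.ndarray
    in_vocabulary: bool
    log_likelihood: float


def _normalize_columns(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=0)
    dead = sums <= 0
    if np.any(dead):
        mat = mat.copy()
        mat[:, dead] = 1.0
        sums = mat.sum(axis=0)
    return mat / sums


def train_plsi(
    corpus: Corpus,
    K: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    beta: float = 1.0,
) -> PLSIModel:
    """Fit the aspect model by EM; deterministic given ``seed``.

    Stops when the relative log-likelihood improvement drops below ``tol``
    or after ``max_iter`` iterations.  The trace holds one value per
    completed iteration and is non-decreasing.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_docs, n_words = corpus.counts.shape
    N = corpus.counts.T  # (W, D)
    doc_totals = corpus.counts.sum(axis=1)
    doc_prior = doc_totals / doc_totals.sum()

    rng = np.random.default_rng(seed)
    p_wt = _normalize_columns(rng.random((n_words, K)) + 0.1)
    p_td = _normalize_columns(rng.random((K, n_docs)) + 0.1)

    log_pd = np.log(np.maximum(doc_prior, PROB_FLOOR))
    trace: list[float] = []
    for _ in range(max_iter):
        a = p_wt if beta == 1.0 else p_wt**beta
        b = p_td if beta == 1.0 else p_td**beta
        mix = a @ b  # ∝ responsibilities denominator; equals P(w|d) when beta=1
        p_wd = p_wt @ p_td
        ll = float(np.sum(N * (np.log(np.maximum(p_wd, PROB_FLOOR)) + log_pd[None, :])))
        if trace and ll - trace[-1] < tol * abs(trace[-1]):
            trace.append(max(ll, trace[-1]))
            break
        trace.append(ll)
        q = np.divide(N, np.maximum(mix, PROB_FLOOR))
        p_wt_new = a * (q @ b.T)
        p_td_new = b * (a.T @ q)
        p_wt = _normalize_columns(p_wt_new)
        p_td = _normalize_columns(p_td_new)
    return PLSIModel(
        K=K,
        documents=list(corpus.documents),
        vocabulary=list(corpus.vocabulary),
        word_given_topic=p_wt,
        topic_given_doc=p_td,
        doc_prior=doc_prior,
        log_likelihood_trace=trace,
        seed=seed,
        beta=beta,
    )


def fold_in(
    model: PLSIModel,
    new_doc_weights: Mapping[str, float],
    max_iter: int = FOLD_IN_MAX_ITER,
    tol: float = 1e-10,
) -> FoldInResult:
    """Estimate ``P(t|d')`` for an unseen document with ``P(w|t)`` frozen.

    Words outside the training vocabulary are ignored; if nothing overlaps,
    a uniform distribution is returned with ``in_vocabulary=False``.
    """
    index = {w: j for j, w in enumerate(model.vocabulary)}
    v = np.zeros(len(model.vocabulary), dtype=float)
    for word, weight in new_doc_weights.items():
        j = index.get(word)
        if j is not None and weight > 0:
            v[j] += weight
    if v.sum() <= 0:
        warnings.warn("document shares no vocabulary with the trained model; returning uniform topics")
        return FoldInResult(np.full(model.K, 1.0 / model.K), False, float("-inf"))
    p_wt = model.word_given_topic
    a = p_wt if model.beta == 1.0 else p_wt**model.beta
    theta = np.full(model.K, 1.0 / model.K)
    for _ in range(max_iter):
        mix = a @ (theta if model.beta == 1.0 else theta**model.beta)
        q = np.divide(v, np.maximum(mix, PROB_FLOOR))
        theta_new = (theta if model.beta == 1.0 else theta**model.beta) * (a.T @ q)
        total = theta_new.sum()
        theta_new = np.full(model.K, 1.0 / model.K) if total <= 0 else theta_new / total
        if np.abs(theta_new - theta).sum() < tol:
            theta = theta_new
            break
        theta = theta_new
    ll = float(np.sum(v * np.log(np.maximum(p_wt @ theta, PROB_FLOOR))))
    return FoldInResult(theta, True, ll)


def corpus_log_likelihood(model: PLSIModel, corpus: Corpus) -> float:
    """Sum over (d, w) of n(d, w) * log P(w, d) under the fitted model."""
    if list(corpus.vocabulary) != list(model.vocabulary) or list(corpus.documents) != list(model.documents):
        raise ValueError("model and corpus disagree on document/vocabulary indexing")
    p_wd = model.word_given_topic @ model.topic_given_doc  # (W, D)
    joint = p_wd * np.maximum(model.doc_prior, PROB_FLOOR)[None, :]
    return float(np.sum(corpus.counts.T * np.log(np.maximum(joint, PROB_FLOOR))))
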