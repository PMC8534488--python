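"""Online nonnegative matrix factorization for topic detection.

The corpus matrix V (F words x N documents) is factored as V ~ W H with
W (F x K) a nonnegative word-topic dictionary and H (K x N) nonnegative
topic loadings.  To scale to corpora that do not fit in memory, fitting
is *online*: documents are cut into sequential mini-batches of ``s``
columns; for each batch the loadings are solved with the previous
dictionary fixed, then the dictionary is refreshed with the loadings
fixed.  Both block updates use multiplicative update rules, which keep
every entry nonnegative and never increase the batch objective
``||V_batch - W H||_F``.

After fitting, per-document loadings are re-inferred against the final
dictionary by nonnegative least squares, the representative topic of a
document is the argmax loading, and topics whose share of documents
falls strictly below the uniform ratio 1/K are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import nnls

from .preprocess import TfIdfMatrix, Vocabulary

__all__ = [
    "UNASSIGNED",
    "OnmfConfig",
    "TopicModel",
    "TopicLoadings",
    "TopicAssignment",
    "TopicRatio",
    "fit_onmf",
    "infer_loadings",
    "assign_topics",
    "topic_ratios",
    "filter_topics",
    "top_words",
]

#: Sentinel topic index for documents with an all-zero loading column.
UNASSIGNED = -1

_EPS = 1e-12


@dataclass(frozen=True)
class OnmfConfig:
    """Fitting configuration.

    ``n_topics`` and ``batch_size`` default to the production settings
    (50 topics, 2000 documents per batch); ``inner_iters`` bounds the
    alternating multiplicative updates per batch, ``tol`` stops them
    early on small relative objective change, and ``n_passes`` is the
    number of sweeps over the corpus (default one, i.e. purely online).
    """

    n_topics: int = 50
    batch_size: int = 2000
    inner_iters: int = 60
    tol: float = 1e-5
    n_passes: int = 1
    seed: int = 0
    shuffle: bool = False

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.batch_size < 1 or self.inner_iters < 1:
            raise ValueError("n_topics, batch_size and inner_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")


@dataclass
class TopicModel:
    """Fitted dictionary: W is F x K, columns L2-normalized."""

    W: np.ndarray
    config: OnmfConfig
    vocab: Vocabulary
    n_batches: int
    objective_log: list[list[float]] = field(default_factory=list)


@dataclass
class TopicLoadings:
    H: np.ndarray  # K x N, nonnegative
    doc_ids: list[str]


@dataclass
class TopicAssignment:
    """Representative topic per document; UNASSIGNED for zero loadings."""

    topics: np.ndarray  # int, length N
    doc_ids: list[str]
    n_topics: int


@dataclass
class TopicRatio:
    ratios: np.ndarray  # length K, sums to 1 over assigned documents
    threshold: float


def _batch_objective_sq(
    vb_sq: float, WtV: np.ndarray, WtW: np.ndarray, H: np.ndarray
) -> float:
    """||Vb - W H||_F^2 without densifying Vb."""
    val = vb_sq - 2.0 * float(np.sum(WtV * H)) + float(np.sum(WtW * (H @ H.T)))
    return max(val, 0.0)


def fit_onmf(V: TfIdfMatrix, config: OnmfConfig) -> TopicModel:
    """Fit the dictionary by sequential mini-batch alternating updates.

    Deterministic given ``config.seed`` and the column order of ``V``.
    """
    X = sp.csc_matrix(V.values)
    F, N = X.shape
    K, s = config.n_topics, config.batch_size
    if X.nnz == 0:
        raise ValueError("corpus matrix is all zero")
    if K > F:
        raise ValueError(f"n_topics={K} exceeds vocabulary size {F}")

    rng = np.random.default_rng(config.seed)
    W = rng.uniform(0.0, 1.0, size=(F, K))
    order = np.arange(N)
    log: list[list[float]] = []
    n_batches = 0

    for _ in range(config.n_passes):
        if config.shuffle:
            rng.shuffle(order)
        for start in range(0, N, s):
            cols = order[start : start + s]
            Vb = X[:, cols]
            vb_sq = float(Vb.multiply(Vb).sum())
            H = rng.uniform(0.0, 1.0, size=(K, len(cols)))
            batch_log: list[float] = []
            prev = np.inf
            for _it in range(config.inner_iters):
                # loadings step: previous dictionary fixed
                WtV = W.T @ Vb
                WtW = W.T @ W
                H *= WtV / (WtW @ H + _EPS)
                # dictionary step: loadings fixed
                VHt = Vb @ H.T
                W *= VHt / (W @ (H @ H.T) + _EPS)
                WtV = W.T @ Vb
                WtW = W.T @ W
                obj = np.sqrt(_batch_objective_sq(vb_sq, np.asarray(WtV), WtW, H))
                batch_log.append(obj)
                if np.isfinite(prev) and prev - obj <= config.tol * max(prev, _EPS):
                    break
                prev = obj
            # remove scale ambiguity so argmax/top-words are well defined
            norms = np.linalg.norm(W, axis=0)
            W /= np.where(norms > 0, norms, 1.0)
            log.append(batch_log)
            n_batches += 1

    return TopicModel(W=W, config=config, vocab=V.vocab, n_batches=n_batches,
                      objective_log=log)


def infer_loadings(model: TopicModel, V: TfIdfMatrix) -> TopicLoadings:
    """Per-document nonnegative least squares against the final dictionary."""
    X = sp.csc_matrix(V.values)
    F, N = X.shape
    if F != model.W.shape[0]:
        raise ValueError(
            f"matrix has {F} word rows but dictionary has {model.W.shape[0]}"
        )
    K = model.W.shape[1]
    H = np.zeros((K, N))
    W = np.ascontiguousarray(model.W)
    for j in range(N):
        col = X[:, j]
        if col.nnz == 0:
            continue
        h, _ = nnls(W, np.asarray(col.todense()).ravel())
        H[:, j] = h
    return TopicLoadings(H=H, doc_ids=list(V.doc_ids))


def assign_topics(load: TopicLoadings) -> TopicAssignment:
    """Argmax topic per document; ties go to the smallest index and
    all-zero columns to :data:`UNASSIGNED`."""
    H = load.H
    topics = np.argmax(H, axis=0).astype(np.int64)
    topics[H.max(axis=0) <= 0.0] = UNASSIGNED
    return TopicAssignment(topics=topics, doc_ids=load.doc_ids,
                           n_topics=H.shape[0])


def topic_ratios(assign: TopicAssignment, n_topics: int | None = None) -> TopicRatio:
    """Share of assigned documents per topic (unassigned excluded)."""
    K = n_topics if n_topics is not None else assign.n_topics
    assigned = assign.topics[assign.topics != UNASSIGNED]
    if assigned.size == 0:
        raise ValueError("no assigned documents")
    counts = np.bincount(assigned, minlength=K).astype(float)
    return TopicRatio(ratios=counts / assigned.size, threshold=1.0 / K)


def filter_topics(ratio: TopicRatio, n_topics: int | None = None) -> list[int]:
    """Topics at or above the uniform share 1/K; strictly-below dropped."""
    K = n_topics if n_topics is not None else ratio.ratios.shape[0]
    cut = 1.0 / K - 1e-12
    return [k for k, r in enumerate(ratio.ratios) if r >= cut]


def top_words(model: TopicModel, topic: int, n: int = 10) -> list[tuple[str, float]]:
    """The ``n`` highest-weight words of a topic column, descending weight,
    ties broken lexicographically; ``n`` is clamped to the vocabulary size."""
    K = model.W.shape[1]
    if not 0 <= topic < K:
        raise ValueError(f"topic index {topic} out of range [0, {K})")
    col = model.W[:, topic]
    n = max(0, min(n, col.shape[0]))
    ranked = sorted(
        zip(model.vocab.words, col), key=lambda wv: (-wv[1], wv[0])
    )
    return [(w, float(v)) for w, v in ranked[:n]]
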