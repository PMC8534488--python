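"""Tokenization and tf-idf encoding of the corpus matrix V (words x docs).

The corpus is encoded as a sparse nonnegative matrix with F vocabulary
rows and N document columns.  The default weight is the classical
unsmoothed form

    v_ij = n_ij * ln(N / N_i)

where ``n_ij`` counts word i in document j and ``N_i`` is the number of
documents containing word i, so a word appearing in every document gets
weight zero.  A smoothed variant (``ln((1+N)/(1+N_i)) + 1``) and L2
column normalization are available behind flags.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "Vocabulary",
    "TfIdfMatrix",
    "default_stopwords",
    "tokenize",
    "build_vocabulary",
    "tfidf_matrix",
    "save_vocabulary",
    "load_vocabulary",
    "save_matrix",
    "load_matrix",
]

_URL = re.compile(r"(?:https?://|www\.)\S+")
_MENTION = re.compile(r"@\w+")
_TOKEN = re.compile(r"[a-z0-9_']+")


def default_stopwords() -> frozenset[str]:
    text = resources.files("trendmine.data").joinpath("stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def tokenize(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Tweet tokenizer: lowercase, drop URLs and @-mentions, keep hashtags
    as their bare word, strip punctuation, drop stopwords and tokens
    shorter than 2 characters."""
    if stopwords is None:
        stopwords = default_stopwords()
    t = text.lower()
    t = _URL.sub(" ", t)
    t = _MENTION.sub(" ", t)
    t = t.replace("#", " ")
    out = []
    for tok in _TOKEN.findall(t):
        tok = tok.strip("'_")
        if len(tok) < 2 or tok in stopwords:
            continue
        out.append(tok)
    return out


@dataclass
class Vocabulary:
    """Ordered vocabulary with document frequencies.

    ``doc_freq[i]`` is the number of documents containing ``words[i]``
    at build time; ``n_docs`` is the corpus size those counts refer to.
    """

    words: list[str]
    doc_freq: np.ndarray
    n_docs: int

    def __post_init__(self) -> None:
        self.doc_freq = np.asarray(self.doc_freq, dtype=np.int64)
        if len(self.words) != len(set(self.words)):
            raise ValueError("vocabulary words must be unique")
        if len(self.words) != self.doc_freq.shape[0]:
            raise ValueError("words and doc_freq length mismatch")
        if self.doc_freq.size and (
            self.doc_freq.min() < 1 or self.doc_freq.max() > self.n_docs
        ):
            raise ValueError("doc_freq out of range [1, n_docs]")

    def __len__(self) -> int:
        return len(self.words)

    @property
    def index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.words)}


@dataclass
class TfIdfMatrix:
    """Sparse nonnegative corpus matrix, F word rows x N document columns."""

    values: sp.csc_matrix
    vocab: Vocabulary
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        if self.values.shape != (len(self.vocab), len(self.doc_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"vocab size {len(self.vocab)} and {len(self.doc_ids)} doc ids"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("tf-idf entries must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_vocabulary(
    docs: list[list[str]], min_df: int = 1, max_df_frac: float = 1.0
) -> Vocabulary:
    """Build a lexicographically ordered vocabulary with df filtering.

    Words are retained when ``min_df <= df <= max_df_frac * N``.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not 0 < max_df_frac <= 1:
        raise ValueError("max_df_frac must be in (0, 1]")
    if not docs:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    n_docs = len(docs)
    df = Counter(w for doc in docs for w in set(doc))
    cutoff = max_df_frac * n_docs
    words = sorted(w for w, c in df.items() if min_df <= c <= cutoff)
    if not words:
        raise ValueError("vocabulary is empty after df filtering")
    return Vocabulary(words, np.array([df[w] for w in words]), n_docs)


def tfidf_matrix(
    docs: list[list[str]],
    vocab: Vocabulary,
    doc_ids: list[str] | None = None,
    smooth: bool = False,
    l2_normalize: bool = False,
) -> TfIdfMatrix:
    """Encode tokenized documents against ``vocab``; OOV words are ignored."""
    if doc_ids is None:
        doc_ids = [str(j) for j in range(len(docs))]
    if len(doc_ids) != len(docs):
        raise ValueError("doc_ids length mismatch")
    if np.any(vocab.doc_freq == 0):
        raise ValueError("inconsistent vocabulary: zero document frequency")

    n, df = vocab.n_docs, vocab.doc_freq.astype(float)
    if smooth:
        idf = np.log((1.0 + n) / (1.0 + df)) + 1.0
    else:
        idf = np.log(n / df)

    index = vocab.index
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, doc in enumerate(docs):
        counts = Counter(doc)
        for w, c in counts.items():
            i = index.get(w)
            if i is None:
                continue
            v = c * idf[i]
            if v != 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(v)
    mat = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(vocab), len(docs)), dtype=float
    )
    if l2_normalize:
        norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=0)).ravel())
        norms[norms == 0] = 1.0
        mat = mat @ sp.diags(1.0 / norms)
    return TfIdfMatrix(mat, vocab, list(doc_ids))


# ---------------------------------------------------------------------------
# Serialization: vocabulary as TSV, matrix as Matrix Market + doc-id sidecar
# ---------------------------------------------------------------------------


def save_vocabulary(vocab: Vocabulary, path: str | Path, header: str = "") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# n_docs={vocab.n_docs}\n")
        for w, c in zip(vocab.words, vocab.doc_freq):
            fh.write(f"{w}\t{c}\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    words, freqs, n_docs = [], [], 0
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            if "n_docs=" in line:
                n_docs = int(line.split("n_docs=")[1])
            continue
        w, c = line.split("\t")
        words.append(w)
        freqs.append(int(c))
    return Vocabulary(words, np.array(freqs), n_docs)


def save_matrix(mat: TfIdfMatrix, mtx_path: str | Path, ids_path: str | Path) -> None:
    mmwrite(str(mtx_path), mat.values)
    Path(ids_path).write_text("\n".join(mat.doc_ids) + "\n", encoding="utf-8")


def load_matrix(
    mtx_path: str | Path, ids_path: str | Path, vocab: Vocabulary
) -> TfIdfMatrix:
    values = sp.csc_matrix(mmread(str(mtx_path)))
    doc_ids = Path(ids_path).read_text(encoding="utf-8").split()
    return TfIdfMatrix(values, vocab, doc_ids)
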