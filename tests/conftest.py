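"""Shared fixtures: synthetic corpora and fitted models reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from trendmine import onmf, preprocess, sentiment, synthetic_data, trends


@pytest.fixture(scope="session")
def easy_corpus():
    """The 'easy' recovery benchmark: 5 anchored topics, 2000 docs, 60 days."""
    return synthetic_data.generate_corpus(synthetic_data.get_preset("easy"))


@pytest.fixture(scope="session")
def easy_encoded(easy_corpus):
    col, _ = easy_corpus
    stop = preprocess.default_stopwords()
    docs = [preprocess.tokenize(t, stop) for t in col.texts()]
    vocab = preprocess.build_vocabulary(docs, min_df=2, max_df_frac=0.95)
    mat = preprocess.tfidf_matrix(docs, vocab, col.doc_ids)
    return docs, vocab, mat


@pytest.fixture(scope="session")
def easy_model(easy_encoded):
    """ONMF fit with 3 surplus columns beyond the 5 planted topics."""
    _, _, mat = easy_encoded
    config = onmf.OnmfConfig(
        n_topics=8, batch_size=2000, inner_iters=400, tol=1e-7, seed=0
    )
    model = onmf.fit_onmf(mat, config)
    loadings = onmf.infer_loadings(model, mat)
    return model, loadings


@pytest.fixture(scope="session")
def easy_emotions(easy_corpus):
    col, _ = easy_corpus
    return sentiment.emotion_matrix(col)


def _emotion_table(preset: str):
    col, truth = synthetic_data.generate_corpus(synthetic_data.get_preset(preset))
    em = sentiment.emotion_matrix(col)
    assign = onmf.TopicAssignment(
        topics=np.zeros(len(col), dtype=np.int64), doc_ids=col.doc_ids, n_topics=1
    )
    return trends.merge_topic_emotion(assign, em, col), truth


@pytest.fixture(scope="session")
def stationary_table():
    return _emotion_table("stationary")


@pytest.fixture(scope="session")
def drift_table():
    return _emotion_table("drift")


def greedy_match_cosine(true_topic_word, model, vocab, n_topics):
    """Mean best-match cosine between planted topic-word vectors and learned
    dictionary columns, greedy one-to-one, compared on the planted-vocabulary
    coordinates (planted distributions are zero outside their vocabulary)."""
    k_true, v_true = true_topic_word.shape
    index = vocab.index
    W_sub = np.zeros((v_true, n_topics))
    for i in range(v_true):
        row = index.get(f"w{i:03d}")
        if row is not None:
            W_sub[i] = model.W[row]
    cos = np.zeros((k_true, n_topics))
    for t in range(k_true):
        tv = true_topic_word[t]
        nt = np.linalg.norm(tv)
        for k in range(n_topics):
            nk = np.linalg.norm(W_sub[:, k])
            cos[t, k] = tv @ W_sub[:, k] / (nt * nk) if nk > 0 else 0.0
    used: set[int] = set()
    total = 0.0
    for t in np.argsort(-cos.max(axis=1)):
        k = max((k for k in range(n_topics) if k not in used), key=lambda k: cos[t, k])
        used.add(k)
        total += cos[t, k]
    return total / k_true, used
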