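"""Online NMF fitting, inference, assignment and topic filtering."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from trendmine import onmf
from trendmine.preprocess import TfIdfMatrix, Vocabulary

from conftest import greedy_match_cosine


def wrap(M):
    """Dress a dense nonnegative array as a TfIdfMatrix."""
    F, N = M.shape
    vocab = Vocabulary(
        [f"w{i:03d}" for i in range(F)], np.ones(F, dtype=int), max(N, 1)
    )
    return TfIdfMatrix(sp.csc_matrix(M), vocab, [str(j) for j in range(N)])


def reference_batch_mu(M, k, iters, seed):
    """Independent plain batch multiplicative-update NMF (same init
    convention: W then H drawn uniform(0,1) from the seed)."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(0, 1, (M.shape[0], k))
    H = rng.uniform(0, 1, (k, M.shape[1]))
    eps = 1e-12
    for _ in range(iters):
        H *= (W.T @ M) / (W.T @ W @ H + eps)
        W *= (M @ H.T) / (W @ H @ H.T + eps)
    return np.linalg.norm(M - W @ H)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_topics": 0},
            {"batch_size": 0},
            {"inner_iters": 0},
            {"tol": 0.0},
            {"n_passes": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            onmf.OnmfConfig(**kwargs)


class TestFit:
    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            onmf.fit_onmf(wrap(np.zeros((4, 5))), onmf.OnmfConfig(n_topics=2))

    def test_too_many_topics_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            onmf.fit_onmf(wrap(np.ones((3, 5))), onmf.OnmfConfig(n_topics=4))

    def test_exact_low_rank_recovered_in_two_passes(self):
        rng = np.random.default_rng(42)
        Wt, Ht = rng.uniform(0, 1, (20, 2)), rng.uniform(0, 1, (2, 200))
        M = Wt @ Ht
        config = onmf.OnmfConfig(
            n_topics=2, batch_size=50, inner_iters=100, n_passes=2, seed=0, tol=1e-9
        )
        model = onmf.fit_onmf(wrap(M), config)
        H = onmf.infer_loadings(model, wrap(M)).H
        rel = np.linalg.norm(M - model.W @ H) / np.linalg.norm(M)
        assert rel <= 0.05

    def test_single_batch_equals_reference_batch_mu(self):
        rng = np.random.default_rng(7)
        M = rng.uniform(0, 1, (30, 5)) @ rng.uniform(0, 1, (5, 120))
        M += rng.uniform(0, 0.05, M.shape)
        iters = 150
        config = onmf.OnmfConfig(
            n_topics=5, batch_size=200, inner_iters=iters, seed=3, tol=1e-15
        )
        model = onmf.fit_onmf(wrap(M), config)
        ours = model.objective_log[0][-1]
        ref = reference_batch_mu(M, 5, iters, seed=3)
        assert ours == pytest.approx(ref, rel=0.01)

    def test_rank_one_matches_truncated_svd(self):
        # for a nonnegative matrix the best rank-1 approximation is
        # nonnegative (Perron-Frobenius), so SVD is an exact oracle
        rng = np.random.default_rng(5)
        M = rng.uniform(0, 1, (30, 40))
        config = onmf.OnmfConfig(
            n_topics=1, batch_size=40, inner_iters=200, seed=0, tol=1e-12
        )
        model = onmf.fit_onmf(wrap(M), config)
        H = onmf.infer_loadings(model, wrap(M)).H
        u, s, vt = svds(M, k=1)
        err_svd = np.linalg.norm(M - u @ np.diag(s) @ vt)
        err_ours = np.linalg.norm(M - model.W @ H)
        assert err_ours == pytest.approx(err_svd, rel=1e-3)

    def test_batch_objective_non_increasing(self, easy_model):
        model, _ = easy_model
        for batch_log in model.objective_log:
            diffs = np.diff(batch_log)
            assert np.all(diffs <= 1e-8 * np.abs(batch_log[:-1]) + 1e-9)

    def test_dictionary_nonnegative_unit_columns(self, easy_model):
        model, _ = easy_model
        assert model.W.min() >= 0
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 1, (15, 40))
        config = onmf.OnmfConfig(n_topics=3, batch_size=10, inner_iters=20, seed=9)
        W1 = onmf.fit_onmf(wrap(M), config).W
        W2 = onmf.fit_onmf(wrap(M), config).W
        assert np.array_equal(W1, W2)


class TestInference:
    def test_dictionary_column_maps_to_unit_loading(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0.1, 1, (10, 3))
        model = onmf.TopicModel(
            W=W, config=onmf.OnmfConfig(n_topics=3), vocab=wrap(W).vocab, n_batches=1
        )
        V = wrap(np.column_stack([2.0 * W[:, 1], np.zeros(10)]))
        load = onmf.infer_loadings(model, V)
        assert load.H[:, 0] == pytest.approx([0.0, 2.0, 0.0], abs=1e-8)
        assert np.all(load.H[:, 1] == 0.0)

    def test_known_loadings_recovered_under_full_rank(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 1, (10, 3))
        h = np.array([[0.5, 0.0, 2.0], [1.0, 1.0, 0.0]]).T
        model = onmf.TopicModel(
            W=W, config=onmf.OnmfConfig(n_topics=3), vocab=wrap(W).vocab, n_batches=1
        )
        load = onmf.infer_loadings(model, wrap(W @ h))
        assert np.allclose(load.H, h, atol=1e-6)

    def test_dimension_mismatch_rejected(self, easy_model):
        model, _ = easy_model
        with pytest.raises(ValueError, match="word rows"):
            onmf.infer_loadings(model, wrap(np.ones((3, 2))))


class TestAssignment:
    def test_argmax_ties_and_sentinel(self):
        H = np.array([[0.1, 0.5, 0.0], [0.9, 0.5, 0.0]])
        load = onmf.TopicLoadings(H=H, doc_ids=["a", "b", "c"])
        assign = onmf.assign_topics(load)
        assert assign.topics.tolist() == [1, 0, onmf.UNASSIGNED]

    def test_assignment_invariant_to_column_rescaling(self, easy_encoded, easy_model):
        _, _, mat = easy_encoded
        model, loadings = easy_model
        rng = np.random.default_rng(4)
        scales = rng.uniform(0.5, 3.0, mat.shape[1])
        scaled = TfIdfMatrix(
            sp.csc_matrix(mat.values @ sp.diags(scales)), mat.vocab, mat.doc_ids
        )
        a1 = onmf.assign_topics(loadings)
        a2 = onmf.assign_topics(onmf.infer_loadings(model, scaled))
        assert np.array_equal(a1.topics, a2.topics)


class TestRatiosAndFilter:
    def test_ratio_example(self):
        assign = onmf.TopicAssignment(
            topics=np.array([0, 0, 1, 2]), doc_ids=list("abcd"), n_topics=3
        )
        ratio = onmf.topic_ratios(assign)
        assert ratio.ratios.tolist() == [0.5, 0.25, 0.25]

    def test_unassigned_excluded_from_denominator(self):
        assign = onmf.TopicAssignment(
            topics=np.array([0, onmf.UNASSIGNED, 0, 1]), doc_ids=list("abcd"),
            n_topics=2,
        )
        assert onmf.topic_ratios(assign).ratios.tolist() == [2 / 3, 1 / 3]

    def test_all_unassigned_rejected(self):
        assign = onmf.TopicAssignment(
            topics=np.array([onmf.UNASSIGNED]), doc_ids=["a"], n_topics=2
        )
        with pytest.raises(ValueError, match="no assigned"):
            onmf.topic_ratios(assign)

    def test_single_topic_monopoly(self):
        assign = onmf.TopicAssignment(
            topics=np.zeros(5, dtype=int), doc_ids=list("abcde"), n_topics=3
        )
        assert onmf.topic_ratios(assign).ratios.tolist() == [1.0, 0.0, 0.0]

    def test_filter_drops_strictly_below_average(self):
        ratios = np.zeros(50)
        ratios[:3] = [0.5, 0.3, 0.2]
        assert onmf.filter_topics(onmf.TopicRatio(ratios, 0.02), 50) == [0, 1, 2]

    def test_uniform_ratios_all_retained(self):
        ratios = np.full(50, 0.02)
        assert onmf.filter_topics(onmf.TopicRatio(ratios, 0.02), 50) == list(range(50))


class TestTopWords:
    def test_single_nonzero_word_ranks_first(self):
        W = np.zeros((4, 2))
        W[2, 0] = 1.0
        W[:, 1] = [0.5, 0.5, 0.0, 0.0]
        model = onmf.TopicModel(
            W=W, config=onmf.OnmfConfig(n_topics=2), vocab=wrap(W).vocab, n_batches=1
        )
        assert onmf.top_words(model, 0, 1)[0][0] == "w002"
        # tie on weight 0.5 -> lexicographic order
        assert [w for w, _ in onmf.top_words(model, 1, 2)] == ["w000", "w001"]

    def test_n_clamped_and_zero(self, easy_model):
        model, _ = easy_model
        assert onmf.top_words(model, 0, 0) == []
        full = onmf.top_words(model, 0, 10**6)
        assert len(full) == model.W.shape[0]

    def test_bad_topic_index_rejected(self, easy_model):
        model, _ = easy_model
        with pytest.raises(ValueError):
            onmf.top_words(model, model.W.shape[1], 3)


class TestPlantedRecovery:
    def test_mean_best_match_cosine(self, easy_corpus, easy_encoded, easy_model):
        _, truth = easy_corpus
        _, vocab, _ = easy_encoded
        model, _ = easy_model
        mean_cos, _ = greedy_match_cosine(truth.topic_word, model, vocab, 8)
        assert mean_cos >= 0.80

    def test_anchor_words_dominate_matched_topics(
        self, easy_corpus, easy_encoded, easy_model
    ):
        col, truth = easy_corpus
        _, vocab, _ = easy_encoded
        model, _ = easy_model
        _, matched = greedy_match_cosine(truth.topic_word, model, vocab, 8)
        # each planted topic's anchors should be prominent in some
        # matched learned column
        hits = 0
        for t, anchors in enumerate(truth.anchor_words):
            best = 0
            for k in matched:
                top = {w for w, _ in onmf.top_words(model, k, 12)}
                best = max(best, len(top & set(anchors)))
            hits += best
        assert hits >= 0.8 * sum(len(a) for a in truth.anchor_words)
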