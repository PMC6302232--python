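"""Vocabulary filtering, collapsed-Gibbs LDA, message topic loads, and
topic-disease correlation with BH control."""

import math

import numpy as np
import pandas as pd
import pytest

from infodem.experiments import bh_null_fdr, lda_block_recovery
from infodem.lexicon import Lexicon
from infodem.topics import (
    TopicModel,
    Vocabulary,
    build_vocabulary,
    fit_lda,
    message_topic_distribution,
    topic_disease_correlations,
)


class TestVocabulary:
    def test_below_threshold_token_excluded(self):
        docs = [("a1", ["rare"])] + [(f"u{i}", ["common"]) for i in range(99)]
        vocab = build_vocabulary(docs, [], min_author_frac=0.05)
        assert "common" in vocab.index and "rare" not in vocab.index

    def test_keyword_removed_despite_high_use(self):
        docs = [(f"u{i}", ["asthma", "inhaler"]) for i in range(10)]
        vocab = build_vocabulary(docs, [Lexicon("asthma", ["asthma"])], 0.05)
        assert "asthma" not in vocab.index and "inhaler" in vocab.index

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            build_vocabulary([], [], 0.05)

    def test_author_fractions_match_bruteforce_recount(self, tiny_pairs, tiny_lexica):
        from infodem.lexicon import tokenize

        docs = [(m.author_id, tokenize(m.text)) for m, _ in tiny_pairs[:50]]
        vocab = build_vocabulary(docs, tiny_lexica, 0.05)
        authors = {a for a, _ in docs}
        kw_tokens = set().union(*(l.all_tokens() for l in tiny_lexica))
        expected = set()
        seen = {t for _, toks in docs for t in toks}
        for tok in seen:
            users = {a for a, toks in docs if tok in toks}
            if len(users) / len(authors) >= 0.05 and tok not in kw_tokens:
                expected.add(tok)
        assert set(vocab.tokens) == expected


@pytest.fixture(scope="module")
def block_model():
    """LDA fit on three disjoint vocabulary blocks (planted structure)."""
    rng = np.random.default_rng(2)
    tokens = [f"b{b}w{i}" for b in range(3) for i in range(10)]
    vocab = Vocabulary(tokens, {t: 1.0 for t in tokens}, 1)
    docs = []
    for _ in range(120):
        b = int(rng.integers(3))
        docs.append([f"b{b}w{i}" for i in rng.integers(10, size=15)])
    return fit_lda(docs, vocab, K=3, alpha=0.1, n_iter=120, burn_in=40, seed=2)


class TestLda:
    def test_recovers_planted_blocks(self):
        assert lda_block_recovery(seed=2) >= 0.90

    def test_phi_rows_and_prior_normalized(self, block_model):
        assert np.allclose(block_model.phi.sum(axis=1), 1.0, atol=1e-9)
        assert block_model.topic_prior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loglik_trend_nondecreasing(self, block_model):
        ll = block_model.loglik
        windows = [ll[i : i + 10].mean() for i in range(0, len(ll) - 9, 10)]
        span = max(windows) - min(windows) + 1e-12
        assert windows[-1] > windows[0]
        assert all(b - a >= -0.05 * span for a, b in zip(windows, windows[1:]))

    def test_k_below_two_rejected(self, block_model):
        with pytest.raises(ValueError):
            fit_lda([["b0w0"]], block_model.vocab, K=1)


class TestMessageTopicLoad:
    def test_single_token_identity(self, block_model):
        p = message_topic_distribution(["b0w3"], block_model)
        w = block_model.vocab.index["b0w3"]
        assert np.allclose(p, block_model.p_topic_given_word()[:, w], atol=1e-12)

    def test_uniform_model_gives_uniform_load(self):
        tokens = ["a", "b", "c"]
        vocab = Vocabulary(tokens, {t: 1.0 for t in tokens}, 1)
        model = TopicModel(4, np.full((4, 3), 1 / 3), np.full(4, 0.25), 0.1, 0.01, vocab, 0, np.empty(0))
        p = message_topic_distribution(["a", "c"], model)
        assert np.allclose(p, 0.25, atol=1e-12)

    def test_matches_bruteforce_double_sum(self, block_model):
        msg = ["b0w1", "b1w2", "b1w2", "b2w5", "b0w0"]
        p = message_topic_distribution(msg, block_model)
        ptw = block_model.p_topic_given_word()
        expected = np.zeros(block_model.K)
        for tok in msg:
            expected += (1 / len(msg)) * ptw[:, block_model.vocab.index[tok]]
        assert np.allclose(p, expected, atol=1e-12)

    def test_invariant_to_duplicating_token_list(self, block_model):
        msg = ["b0w1", "b1w2", "b2w5"]
        assert np.allclose(
            message_topic_distribution(msg, block_model),
            message_topic_distribution(msg * 3, block_model),
            atol=1e-12,
        )

    def test_out_of_vocabulary_message_flagged(self, block_model):
        assert message_topic_distribution(["zzz"], block_model) is None


def _bh_stepup(pvals):
    """Independent hand implementation of the BH step-up adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, pvals[idx] * m / rank)
        adj[idx] = prev
    return adj


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(4)
    n, K = 120, 6
    loads = rng.dirichlet(np.ones(K), size=n)
    labels = (rng.random(n) < 0.4).astype(int)
    loads[labels == 1, 2] += 0.5  # planted enrichment on topic 2
    loads /= loads.sum(axis=1, keepdims=True)
    ldf = pd.DataFrame(loads, index=[f"m{i}" for i in range(n)])
    ydf = pd.DataFrame({"asthma": labels}, index=ldf.index)
    return topic_disease_correlations(ldf, ydf), ldf, ydf


class TestCorrelations:
    def test_adjusted_pvalues_match_hand_stepup(self, fitted):
        corr, _, _ = fitted
        adj = _bh_stepup(corr["p"].to_numpy())
        assert np.allclose(corr["p_adj"].to_numpy(), adj, atol=1e-12)

    def test_planted_topic_has_maximal_correlation(self, fitted):
        corr, _, _ = fitted
        top = corr.sort_values("r", ascending=False).iloc[0]
        assert top["topic"] == 2 and top["significant"]

    def test_invariant_to_message_order(self, fitted):
        corr, ldf, ydf = fitted
        perm = ldf.sample(frac=1.0, random_state=9).index
        corr2 = topic_disease_correlations(ldf.loc[perm], ydf.loc[perm])
        a = corr.sort_values(["disease", "topic"]).reset_index(drop=True)
        b = corr2.sort_values(["disease", "topic"]).reset_index(drop=True)
        assert np.allclose(a["r"], b["r"], atol=1e-12)

    def test_zero_variance_topic_is_na_and_out_of_family(self):
        rng = np.random.default_rng(5)
        loads = pd.DataFrame(
            {0: np.full(50, 0.5), 1: rng.random(50)}, index=[f"m{i}" for i in range(50)]
        )
        labels = pd.DataFrame({"d": rng.integers(0, 2, 50)}, index=loads.index)
        corr = topic_disease_correlations(loads, labels)
        na_row = corr[corr["topic"] == 0].iloc[0]
        assert math.isnan(na_row["r"]) and math.isnan(na_row["p_adj"])
        assert not na_row["significant"]

    def test_nonbinary_labels_rejected(self, fitted):
        _, ldf, _ = fitted
        bad = pd.DataFrame({"d": np.linspace(0, 2, len(ldf))}, index=ldf.index)
        with pytest.raises(ValueError):
            topic_disease_correlations(ldf, bad)

    def test_null_family_controls_fdr(self):
        frac, n_pairs = bh_null_fdr(seed=3, n_messages=100, n_diseases=10, n_topics=50)
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_pairs)
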