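"""Vocabulary construction, collapsed-Gibbs LDA, and topic-disease correlation.

The vocabulary keeps tokens used by at least 5% of distinct authors
and drops every token of every disease keyword phrase, so topics
describe the language *around* disease mentions rather than the
mentions themselves.

LDA is fitted by collapsed Gibbs sampling: token-topic assignments are
resampled from

    p(z_i = k | ...) ∝ (n_dk + α) · (n_kw + β) / (n_k + Vβ)

and the topic-word matrix φ and topic marginal p(topic) are estimated
from post-burn-in count averages with β/α smoothing.  The per-message
topic distribution follows the word-level Bayes inversion

    p(t | message) = Σ_w p(w | message) · p(t | w),
    p(t | w) ∝ φ[t, w] · p(t),

with p(w | message) the token's relative frequency among the message's
in-vocabulary tokens.

Topic use is associated with diseases by the Pearson correlation of
the topic-load vector against a binary contains-the-disease label
(point-biserial), with Benjamini-Hochberg control over the whole
(disease, topic) family.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numba
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from infodem.lexicon import Lexicon

log = logging.getLogger(__name__)


@dataclass
class Vocabulary:
    """Retained tokens with author-frequency bookkeeping."""

    tokens: list[str]
    author_frac: dict[str, float]  # over all seen tokens, retained or not
    n_authors: int
    removed_keywords: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def table(self) -> pd.DataFrame:
        rows = [
            (t, f, t in self.index, t in self.removed_keywords)
            for t, f in sorted(self.author_frac.items())
        ]
        return pd.DataFrame(rows, columns=["token", "author_frac", "retained", "is_keyword"])


def build_vocabulary(
    docs: Iterable[tuple[str, list[str]]],
    lexica: Sequence[Lexicon],
    min_author_frac: float = 0.05,
) -> Vocabulary:
    """Vocabulary from (author_id, tokens) pairs.

    Author frequency is computed over *distinct* author ids; disease
    keyword tokens are removed unconditionally.
    """
    authors_of: dict[str, set[str]] = {}
    all_authors: set[str] = set()
    for author, tokens in docs:
        all_authors.add(author)
        for t in set(tokens):
            authors_of.setdefault(t, set()).add(author)
    if not all_authors:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    kw_tokens = set().union(*(lex.all_tokens() for lex in lexica)) if lexica else set()
    n = len(all_authors)
    frac = {t: len(a) / n for t, a in authors_of.items()}
    retained = sorted(t for t, f in frac.items() if f >= min_author_frac and t not in kw_tokens)
    removed = {t for t in frac if t in kw_tokens}
    return Vocabulary(retained, frac, n, removed)


@numba.njit(cache=True)
def _gibbs(doc_of, word_of, D, V, K, alpha, beta, n_iter, burn_in, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = doc_of.shape[0]
    z = np.empty(N, np.int64)
    ndk = np.zeros((D, K), np.float64)
    nkw = np.zeros((K, V), np.float64)
    nk = np.zeros(K, np.float64)
    nd = np.zeros(D, np.float64)
    for i in range(N):
        t = np.random.randint(0, K)
        z[i] = t
        ndk[doc_of[i], t] += 1.0
        nkw[t, word_of[i]] += 1.0
        nk[t] += 1.0
        nd[doc_of[i]] += 1.0
    acc_nkw = np.zeros((K, V), np.float64)
    acc_nk = np.zeros(K, np.float64)
    loglik = np.empty(n_iter, np.float64)
    cum = np.empty(K, np.float64)
    for it in range(n_iter):
        for i in range(N):
            d = doc_of[i]
            w = word_of[i]
            t = z[i]
            ndk[d, t] -= 1.0
            nkw[t, w] -= 1.0
            nk[t] -= 1.0
            total = 0.0
            for k in range(K):
                total += (ndk[d, k] + alpha) * (nkw[k, w] + beta) / (nk[k] + V * beta)
                cum[k] = total
            u = np.random.random() * total
            tnew = 0
            while tnew < K - 1 and cum[tnew] < u:
                tnew += 1
            z[i] = tnew
            ndk[d, tnew] += 1.0
            nkw[tnew, w] += 1.0
            nk[tnew] += 1.0
        ll = K * (math.lgamma(V * beta) - V * math.lgamma(beta))
        for k in range(K):
            s = 0.0
            for v in range(V):
                s += math.lgamma(nkw[k, v] + beta)
            ll += s - math.lgamma(nk[k] + V * beta)
        ll += D * (math.lgamma(K * alpha) - K * math.lgamma(alpha))
        for d in range(D):
            s = 0.0
            for k in range(K):
                s += math.lgamma(ndk[d, k] + alpha)
            ll += s - math.lgamma(nd[d] + K * alpha)
        loglik[it] = ll
        if it >= burn_in:
            acc_nkw += nkw
            acc_nk += nk
    S = n_iter - burn_in
    if S < 1:
        S = 1
        acc_nkw += nkw
        acc_nk += nk
    return z, acc_nkw / S, acc_nk / S, loglik


@dataclass
class TopicModel:
    K: int
    phi: np.ndarray  # K x V, rows sum to 1
    topic_prior: np.ndarray  # p(topic), sums to 1
    alpha: float
    beta: float
    vocab: Vocabulary
    seed: int
    loglik: np.ndarray  # per-iteration collapsed joint log-likelihood
    z: np.ndarray | None = None  # final token-topic assignment state

    def __post_init__(self) -> None:
        self._p_topic_given_word: np.ndarray | None = None

    def p_topic_given_word(self) -> np.ndarray:
        """K x V posterior p(t|w) ∝ φ[t,w]·p(t); all-zero columns fall back to uniform."""
        if self._p_topic_given_word is None:
            a = self.phi * self.topic_prior[:, None]
            col = a.sum(axis=0)
            safe = np.where(col > 0, col, 1.0)
            p = a / safe
            p[:, col <= 0] = 1.0 / self.K
            self._p_topic_given_word = p
        return self._p_topic_given_word

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.save(outdir / "phi.npy", self.phi)
        np.save(outdir / "topic_prior.npy", self.topic_prior)
        pd.DataFrame({"token": self.vocab.tokens}).to_csv(outdir / "vocabulary.csv", index=False)
        meta = {"K": self.K, "alpha": self.alpha, "beta": self.beta, "seed": self.seed}
        (outdir / "model.json").write_text(json.dumps(meta, indent=2))


def fit_lda(
    docs: Sequence[list[str]],
    vocab: Vocabulary,
    K: int = 200,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 400,
    burn_in: int = 150,
    seed: int = 0,
    n_restarts: int = 1,
) -> TopicModel:
    """Collapsed-Gibbs LDA over tokenized documents.

    ``alpha`` defaults to 50/K.  Out-of-vocabulary tokens are dropped;
    documents with no in-vocabulary tokens are skipped.  The same seed
    reproduces the fit exactly.

    A single Gibbs chain can stick in a label-merged mode on strongly
    multimodal corpora; ``n_restarts`` > 1 runs that many independent
    chains (seeds derived from ``seed``) and keeps the one with the
    highest mean post-burn-in joint log-likelihood.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    V = len(vocab)
    if V == 0:
        raise ValueError("empty vocabulary")
    if V < K:
        log.warning("vocabulary size %d is smaller than K=%d", V, K)
    if alpha is None:
        alpha = 50.0 / K
    doc_ids: list[int] = []
    word_ids: list[int] = []
    D = 0
    for tokens in docs:
        ids = [vocab.index[t] for t in tokens if t in vocab.index]
        if not ids:
            continue
        doc_ids.extend([D] * len(ids))
        word_ids.extend(ids)
        D += 1
    if D == 0:
        raise ValueError("no documents with in-vocabulary tokens")
    doc_arr = np.asarray(doc_ids, dtype=np.int64)
    word_arr = np.asarray(word_ids, dtype=np.int64)
    best = None
    for r in range(max(1, int(n_restarts))):
        chain_seed = (int(seed) + 7919 * r) & 0x7FFFFFFF
        result = _gibbs(doc_arr, word_arr, D, V, K, float(alpha), float(beta),
                        int(n_iter), int(burn_in), chain_seed)
        score = float(result[3][burn_in:].mean()) if n_iter > burn_in else float(result[3][-1])
        if best is None or score > best[0]:
            best = (score, result)
    z, mean_nkw, mean_nk, loglik = best[1]
    phi = (mean_nkw + beta) / (mean_nk + V * beta)[:, None]
    phi /= phi.sum(axis=1, keepdims=True)
    prior = (mean_nk + alpha) / (mean_nk.sum() + K * alpha)
    return TopicModel(K, phi, prior, float(alpha), float(beta), vocab, int(seed), loglik, z)


def message_topic_distribution(tokens: list[str], model: TopicModel) -> np.ndarray | None:
    """p(topic|message) = Σ_w p(w|message)·p(t|w); None if no token is in vocabulary."""
    idx = [model.vocab.index[t] for t in tokens if t in model.vocab.index]
    if not idx:
        return None
    ids, counts = np.unique(np.asarray(idx), return_counts=True)
    freq = counts / counts.sum()
    return model.p_topic_given_word()[:, ids] @ freq


def corpus_topic_loads(
    messages: Iterable[tuple[str, list[str]]],
    model: TopicModel,
) -> pd.DataFrame:
    """Topic-load matrix over (message_id, tokens) pairs; undefined messages are dropped."""
    rows, ids = [], []
    n_undefined = 0
    for mid, tokens in messages:
        p = message_topic_distribution(tokens, model)
        if p is None:
            n_undefined += 1
            continue
        ids.append(mid)
        rows.append(p)
    if n_undefined:
        log.info("%d messages had no in-vocabulary tokens and were excluded", n_undefined)
    return pd.DataFrame(np.asarray(rows), index=pd.Index(ids, name="message_id"))


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of each column of X against y (NaN where undefined)."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = math.sqrt(float((yc**2).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.where((sx > 0) & (sy > 0), r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
    return r, p


def topic_disease_correlations(
    loads: pd.DataFrame,
    disease_labels: pd.DataFrame,
    alpha_level: float = 0.001,
) -> pd.DataFrame:
    """Point-biserial correlation of every (disease, topic) pair with BH control.

    ``loads``: messages x topics; ``disease_labels``: messages x
    diseases, binary.  BH is applied once over the full family of
    defined pairs; pairs with zero variance on either side are NA and
    excluded from the family.  Output is sorted by |r| descending.
    """
    common = loads.index.intersection(disease_labels.index)
    if len(common) < 3:
        raise ValueError("need at least 3 messages with defined topic loads and labels")
    X = loads.loc[common].to_numpy(dtype=float)
    records = []
    for disease in disease_labels.columns:
        y = disease_labels.loc[common, disease].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"labels for {disease!r} must be binary")
        r, p = _pearson_columns(X, y)
        for topic in range(X.shape[1]):
            records.append((disease, topic, r[topic], p[topic]))
    df = pd.DataFrame(records, columns=["disease", "topic", "r", "p"])
    df["p_adj"] = np.nan
    defined = df["p"].notna()
    if defined.any():
        _, p_adj, _, _ = multipletests(df.loc[defined, "p"], method="fdr_bh")
        df.loc[defined, "p_adj"] = p_adj
    df["significant"] = df["p_adj"] < alpha_level
    return df.reindex(df["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
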