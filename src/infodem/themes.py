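"""Theme clustering of LDA topics by NMF, with PMI disease-theme association.

The K x V topic-word matrix φ is factorized as φ ≈ W·H with W (K x T)
giving each topic's weight on each of T themes and H (T x V) the
theme-level word weights.  Multiplicative updates minimize the
Frobenius reconstruction error from a nonnegative-double-SVD
initialization, so the error is non-increasing across iterations.

From the factorization:

* p(word|theme) — row-normalized H;
* theme prior p(theme) ∝ column mass of W;
* p(theme|word) by Bayes' rule, p(t|w) ∝ p(w|t)·p(t);
* per-message theme distributions by the same word-mixing rule as the
  topic distributions, with a hard argmax theme assignment.

Disease-theme association is reported two ways: p(theme|disease) from
hard-assignment counts, and the pointwise mutual information

    PMI(d, t) = log[ p(d, t) / (p(d)·p(t)) ]

over the disease-message universe (natural log by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from infodem._util import round_half_up
from infodem.topics import TopicModel

log = logging.getLogger(__name__)

DEFAULT_THEME_NAMES = [
    "News",
    "Research",
    "Slang or Popular Culture Reference",
    "Environment",
    "Diagnosis and Survivorship",
    "Treatment",
    "Diet and Prevention",
    "Awareness",
    "Risk Factor",
    "Personal Experience",
]


def _nndsvd_init(X: np.ndarray, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization (zeros filled with a small mean term).

    Deterministic: SVD signs are fixed so each singular vector's
    largest-magnitude entry is positive.
    """
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    K, V = X.shape
    W = np.zeros((K, T))
    H = np.zeros((T, V))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, min(T, len(s))):
        u, v = U[:, j], Vt[j, :]
        if abs(u.min()) > abs(u.max()):
            u, v = -u, -v
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            if sigma > 0:
                W[:, j] = np.sqrt(s[j] * sigma) * up / n_up
                H[j, :] = np.sqrt(s[j] * sigma) * vp / n_vp
        else:
            sigma = n_un * n_vn
            if sigma > 0:
                W[:, j] = np.sqrt(s[j] * sigma) * un / n_un
                H[j, :] = np.sqrt(s[j] * sigma) * vn / n_vn
    fill = X.mean() / 100.0 + 1e-12
    W[W <= 0] = fill
    H[H <= 0] = fill
    return W, H


def _multiplicative_updates(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, n_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    eps = 1e-12
    residuals = np.empty(n_iter)
    prev = None
    for it in range(n_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        residuals[it] = np.linalg.norm(X - W @ H)
        if prev is not None and abs(prev - residuals[it]) <= tol * max(prev, 1e-30):
            residuals = residuals[: it + 1]
            break
        prev = residuals[it]
    return W, H, residuals


@dataclass
class ThemeModel:
    T: int
    W: np.ndarray  # K x T topic-to-theme weights, nonnegative
    H: np.ndarray  # T x V raw factor
    word_given_theme: np.ndarray  # T x V, rows sum to 1
    theme_prior: np.ndarray  # length T, sums to 1
    theme_given_word: np.ndarray  # V x T, rows sum to 1
    names: list[str]
    seed: int
    residuals: np.ndarray  # reconstruction error per update iteration
    vocab_tokens: list[str] = field(default_factory=list)

    def topic_theme(self) -> np.ndarray:
        """Row-normalized W: each topic's distribution over themes."""
        rs = self.W.sum(axis=1, keepdims=True)
        out = np.where(rs > 0, self.W / np.where(rs > 0, rs, 1.0), 1.0 / self.T)
        return out


def fit_themes(
    model: TopicModel,
    T: int = 10,
    seed: int = 0,
    n_iter: int = 500,
    tol: float = 1e-9,
    names: Sequence[str] | None = None,
) -> ThemeModel:
    """NMF of the topic-word matrix into T themes.

    Theme names are configuration strings (the canonical 10 labels by
    default); they carry no semantics for any computation.
    """
    K = model.K
    if not (2 <= T <= K):
        raise ValueError(f"theme count T={T} must satisfy 2 <= T <= K={K}")
    X = model.phi.astype(float)
    W, H = _nndsvd_init(X, T)
    W, H, residuals = _multiplicative_updates(X, W, H, n_iter, tol)
    if len(residuals) == n_iter and n_iter > 1 and residuals[-2] - residuals[-1] > tol * residuals[-2]:
        log.warning("NMF did not converge in %d iterations; final residual %.3e", n_iter, residuals[-1])
    hs = H.sum(axis=1, keepdims=True)
    word_given_theme = np.where(hs > 0, H / np.where(hs > 0, hs, 1.0), 1.0 / H.shape[1])
    col_mass = W.sum(axis=0)
    theme_prior = col_mass / col_mass.sum() if col_mass.sum() > 0 else np.full(T, 1.0 / T)
    joint = word_given_theme.T * theme_prior[None, :]  # V x T
    rows = joint.sum(axis=1, keepdims=True)
    theme_given_word = np.where(rows > 0, joint / np.where(rows > 0, rows, 1.0), 1.0 / T)
    if names is None:
        names = DEFAULT_THEME_NAMES if T == len(DEFAULT_THEME_NAMES) else [f"theme_{i}" for i in range(T)]
    if len(names) != T:
        raise ValueError(f"expected {T} theme names, got {len(names)}")
    return ThemeModel(
        T, W, H, word_given_theme, theme_prior, theme_given_word,
        list(names), int(seed), residuals, list(model.vocab.tokens),
    )


@dataclass(frozen=True)
class MessageThemeLoad:
    message_id: str
    p_theme: np.ndarray  # length T, sums to 1
    assigned_theme: int  # argmax, lowest index on ties


def message_theme_distribution(
    tokens: list[str], themes: ThemeModel, vocab_index: Mapping[str, int], message_id: str = ""
) -> MessageThemeLoad | None:
    """p(theme|message) = Σ_w p(w|message)·p(theme|w); None when no token is in vocabulary."""
    idx = [vocab_index[t] for t in tokens if t in vocab_index]
    if not idx:
        return None
    ids, counts = np.unique(np.asarray(idx), return_counts=True)
    freq = counts / counts.sum()
    p = freq @ themes.theme_given_word[ids, :]
    return MessageThemeLoad(message_id, p, int(np.argmax(p)))


def corpus_theme_loads(
    messages: Iterable[tuple[str, list[str]]],
    themes: ThemeModel,
    vocab_index: Mapping[str, int],
) -> pd.DataFrame:
    rows = []
    for mid, tokens in messages:
        load = message_theme_distribution(tokens, themes, vocab_index, mid)
        if load is None:
            continue
        rows.append((mid, load.assigned_theme, *load.p_theme))
    cols = ["message_id", "assigned_theme"] + [f"p_theme_{i}" for i in range(themes.T)]
    return pd.DataFrame(rows, columns=cols).set_index("message_id")


def theme_given_disease(
    theme_loads: pd.DataFrame,
    disease_labels: pd.DataFrame,
    theme_names: Sequence[str] | None = None,
    soft: bool = False,
) -> pd.DataFrame:
    """Per-disease theme distribution from hard assignments.

    Rows: (disease, theme, theme_name, n, n_disease, p_pct) with
    p(t|d) = N(d,t)/N(d) as a percentage to 2 decimals.  ``soft``
    replaces hard counts by mean theme probability mass (reported in
    the ``p_pct`` column; ``n`` is then the rounded expected count).
    """
    common = theme_loads.index.intersection(disease_labels.index)
    T = int(theme_loads["assigned_theme"].max()) + 1 if len(theme_loads) else 0
    pcols = [c for c in theme_loads.columns if c.startswith("p_theme_")]
    if pcols:
        T = len(pcols)
    records = []
    for disease in disease_labels.columns:
        ids = common[disease_labels.loc[common, disease] == 1]
        n_d = len(ids)
        if n_d == 0:
            log.warning("disease %r has zero messages with defined theme loads; omitted", disease)
            continue
        if soft:
            mass = theme_loads.loc[ids, pcols].to_numpy(dtype=float).sum(axis=0)
            for t in range(T):
                records.append((disease, t, mass[t], n_d))
        else:
            counts = theme_loads.loc[ids, "assigned_theme"].value_counts()
            for t in range(T):
                records.append((disease, t, float(counts.get(t, 0)), n_d))
    df = pd.DataFrame(records, columns=["disease", "theme", "n", "n_disease"])
    df["n"] = df["n"].round(6)
    df["p_pct"] = [round_half_up(100.0 * n / nd, 2) for n, nd in zip(df["n"], df["n_disease"])]
    if theme_names is not None:
        df.insert(2, "theme_name", [theme_names[t] for t in df["theme"]])
    return df


def pmi_disease_theme(stats: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Add PMI(d,t) = log[p(d,t)/(p(d)p(t))] to a theme_given_disease table.

    Probabilities come from the same hard-assignment joint counts; the
    universe is all (disease, message) pairs, so a message about two
    diseases contributes to both.  Natural log unless ``base`` given;
    zero joint counts yield NA.
    """
    df = stats.copy()
    N = df["n"].sum()
    if N <= 0:
        raise ValueError("empty joint count table")
    n_d = df.groupby("disease")["n"].transform("sum")
    n_t = df.groupby("theme")["n"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((df["n"] / N) / ((n_d / N) * (n_t / N)))
    if base is not None:
        pmi = pmi / np.log(base)
    pmi = pmi.where((df["n"] > 0) & (n_d > 0) & (n_t > 0))
    if ((n_d <= 0) | (n_t <= 0)).any():
        log.warning("some disease or theme marginals are zero; PMI reported as NA there")
    df["pmi"] = pmi
    return df
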