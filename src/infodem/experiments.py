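"""Validation experiments on synthetic data with planted ground truth.

Each function builds a small synthetic scenario, runs the relevant
pipeline stage(s), and returns the measured recovery/calibration
quantity.  They are the package's evidence that each statistical stage
does what it claims under the conditions the generator emulates:

* collapsed-Gibbs LDA recovers planted disjoint vocabulary blocks;
* NMF theme clustering recovers block-separable topic groups;
* Benjamini-Hochberg keeps the false-discovery fraction at the nominal
  level on a pure-null topic/label family;
* the correction-factor estimator is an unbiased precision estimate;
* a planted over-represented (disease, theme) pair surfaces with
  above-median PMI after the full LDA -> NMF -> PMI chain;
* the demo pipeline is deterministic end to end.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from infodem.corpus import Message
from infodem.lexicon import MatchedMessage, filter_corpus, lexica_from_mapping, tokenize
from infodem.synthetic import GeneratorConfig, generate_corpus
from infodem.themes import corpus_theme_loads, fit_themes, pmi_disease_theme, theme_given_disease
from infodem.topics import (
    TopicModel,
    Vocabulary,
    build_vocabulary,
    fit_lda,
    topic_disease_correlations,
)


def _plain_vocab(tokens: list[str]) -> Vocabulary:
    return Vocabulary(list(tokens), {t: 1.0 for t in tokens}, 1)


def lda_block_recovery(
    seed: int,
    n_blocks: int = 3,
    words_per_block: int = 10,
    n_docs: int = 120,
    doc_len: int = 15,
    n_iter: int = 120,
    burn_in: int = 40,
) -> float:
    """Fit LDA (K = number of blocks) on documents drawn from disjoint
    vocabulary blocks; return the minimum, over blocks, of the aligned
    topic's probability mass on its block (1.0 = perfect recovery)."""
    rng = np.random.default_rng(seed)
    vocab_tokens = [f"b{b}w{i}" for b in range(n_blocks) for i in range(words_per_block)]
    vocab = _plain_vocab(vocab_tokens)
    docs = []
    for _ in range(n_docs):
        b = int(rng.integers(n_blocks))
        ids = rng.integers(words_per_block, size=doc_len)
        docs.append([f"b{b}w{i}" for i in ids])
    # weakly-informative alpha: each document truly uses one topic, so the
    # 50/K convention (meant for K in the hundreds) would swamp the counts;
    # 3 restarts guard against the occasional label-merged Gibbs mode
    model = fit_lda(docs, vocab, K=n_blocks, alpha=0.1, n_iter=n_iter, burn_in=burn_in,
                    seed=seed, n_restarts=3)
    block_mass = np.stack(
        [model.phi[:, b * words_per_block : (b + 1) * words_per_block].sum(axis=1) for b in range(n_blocks)],
        axis=1,
    )  # K x n_blocks
    # greedy best-match alignment of topics to blocks
    mass = block_mass.copy()
    aligned = []
    for _ in range(n_blocks):
        k, b = np.unravel_index(np.argmax(mass), mass.shape)
        aligned.append(block_mass[k, b])
        mass[k, :] = -1.0
        mass[:, b] = -1.0
    return float(min(aligned))


def nmf_block_recovery(seed: int, K: int = 4, half_vocab: int = 20) -> float:
    """Topic-word matrix with two exactly block-separable topic groups,
    clustered into T=2 themes; return the fraction of topics whose
    dominant theme matches their block's majority theme (1.0 = perfect
    2-cluster recovery)."""
    rng = np.random.default_rng(seed)
    V = 2 * half_vocab
    phi = np.zeros((K, V))
    groups = np.array([0] * (K // 2) + [1] * (K - K // 2))
    for k in range(K):
        block = rng.dirichlet(np.ones(half_vocab))
        lo = groups[k] * half_vocab
        phi[k, lo : lo + half_vocab] = block
    vocab = _plain_vocab([f"v{i}" for i in range(V)])
    model = TopicModel(K, phi, np.full(K, 1.0 / K), 50.0 / K, 0.01, vocab, seed, np.empty(0))
    themes = fit_themes(model, T=2, seed=seed)
    dominant = themes.W.argmax(axis=1)
    correct = 0
    for g in (0, 1):
        members = dominant[groups == g]
        majority = np.bincount(members, minlength=2).argmax()
        other = dominant[groups != g]
        other_majority = np.bincount(other, minlength=2).argmax()
        if majority != other_majority:
            correct += int((members == majority).sum())
    return correct / K


def bh_null_fdr(
    seed: int,
    n_messages: int = 200,
    n_diseases: int = 50,
    n_topics: int = 100,
    level: float = 0.05,
) -> tuple[float, int]:
    """Fraction of (disease, topic) pairs declared significant at
    ``p_adj < level`` when topic loads and labels are independent by
    construction.  Returns (fraction, number of pairs tested)."""
    rng = np.random.default_rng(seed)
    loads = pd.DataFrame(
        rng.dirichlet(np.ones(n_topics), size=n_messages),
        index=[f"m{i}" for i in range(n_messages)],
    )
    labels = pd.DataFrame(
        rng.integers(0, 2, size=(n_messages, n_diseases)),
        index=loads.index,
        columns=[f"d{j}" for j in range(n_diseases)],
    )
    corr = topic_disease_correlations(loads, labels, alpha_level=0.001)
    defined = corr["p_adj"].notna()
    frac = float((corr.loc[defined, "p_adj"] < level).mean())
    return frac, int(defined.sum())


def correction_estimator_bias(
    seed: int,
    pool_size: int = 2000,
    true_precision: float = 0.7,
    n_resamples: int = 200,
    sample_size: int = 30,
) -> dict[str, float]:
    """Repeatedly sample-and-annotate a keyword pool with planted
    relevance; returns the mean estimated w_k, the pool's empirical
    relevant fraction (the estimand of the finite-pool sampler), and
    the standard error of the mean estimate."""
    from infodem.correction import estimate_correction_factor, sample_for_annotation
    from infodem.corpus import MessageTruth

    rng = np.random.default_rng(seed)
    matched, truth = [], {}
    for i in range(pool_size):
        mid = f"m{i:05d}"
        msg = Message(mid, f"u{i}", "2014-01-01T00:00:00Z", "stroke w01")
        matched.append(MatchedMessage(msg, [("stroke", "stroke", 0)]))
        rel = bool(rng.random() < true_precision)
        truth[mid] = MessageTruth(mid, "alder", 0, 0, ["stroke"] if rel else [], [("stroke", rel)])
    pool_frac = sum(any(r for _, r in truth[m.message.message_id].keyword_uses) for m in matched) / pool_size
    estimates = []
    for j in range(n_resamples):
        s = sample_for_annotation(matched, "stroke", "stroke", size=sample_size, seed=seed * 100003 + j, truth=truth)
        estimates.append(estimate_correction_factor(s).w)
    estimates = np.asarray(estimates)
    se_mean = float(np.sqrt(true_precision * (1 - true_precision) / sample_size) / np.sqrt(n_resamples))
    return {
        "mean_w": float(estimates.mean()),
        "pool_frac": float(pool_frac),
        "se_mean": se_mean,
        "true_precision": true_precision,
    }


def planted_pmi_config(seed: int) -> GeneratorConfig:
    """Scenario with one planted over-represented (disease, theme) pair:
    asthma messages draw theme 0 with an 8x prior weight."""
    return GeneratorConfig(
        n_users=250,
        n_messages=1500,
        lexicon={"asthma": ["asthma"], "stroke": ["stroke"], "diabetes": ["diabetes"]},
        keyword_relevance={"asthma": 0.95, "stroke": 0.9, "diabetes": 0.9},
        n_themes=4,
        n_topics=12,
        vocab_size=300,
        theme_topic_conc=0.05,
        topic_word_conc=0.05,
        disease_theme_bias={"asthma": {0: 8.0}},
        keyword_rate=0.45,
        seed=seed,
    )


def pmi_planted_recovery(seed: int) -> dict[str, float]:
    """Full LDA -> NMF -> PMI chain on a corpus with one planted
    over-represented (asthma, theme) pair; returns that pair's PMI
    (after aligning the planted theme to its majority fitted theme)
    and the disease's median PMI across fitted themes."""
    cfg = planted_pmi_config(seed)
    pairs = list(generate_corpus(cfg))
    msgs = [(m.message_id, m.author_id, tokenize(m.text)) for m, _ in pairs]
    truth = {t.message_id: t for _, t in pairs}
    lexica = lexica_from_mapping(cfg.lexicon)
    filt = filter_corpus([m for m, _ in pairs], lexica)
    vocab = build_vocabulary(((a, toks) for _, a, toks in msgs), lexica, 0.02)
    model = fit_lda([toks for _, _, toks in msgs], vocab, K=cfg.n_topics, n_iter=150, burn_in=50, seed=seed)
    themes = fit_themes(model, T=cfg.n_themes, seed=seed)
    loads = corpus_theme_loads(((mid, toks) for mid, _, toks in msgs), themes, vocab.index)
    labels = pd.DataFrame(0, index=loads.index, columns=[l.disease for l in lexica])
    for mm in filt.matched:
        mid = mm.message.message_id
        if mid in labels.index:
            for d in mm.diseases():
                labels.loc[mid, d] = 1
    stats = pmi_disease_theme(theme_given_disease(loads, labels))
    planted_ids = [mid for mid in loads.index if truth[mid].theme == 0]
    fitted_theme = int(loads.loc[planted_ids, "assigned_theme"].mode().iloc[0])
    sub = stats[stats["disease"] == "asthma"]
    return {
        "planted_pair_pmi": float(sub.loc[sub["theme"] == fitted_theme, "pmi"].iloc[0]),
        "median_pmi": float(sub["pmi"].median()),
        "fitted_theme": fitted_theme,
    }


def _tree_checksums(outdir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(Path(outdir).glob("*.csv")):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def demo_pipeline_determinism(workdir: str | Path, seed: int = 7) -> dict[str, object]:
    """Run the bundled demo pipeline twice with the same seed; return
    whether every CSV artifact is byte-identical plus the checksums."""
    from importlib import resources

    from infodem.pipeline import run_pipeline

    workdir = Path(workdir)
    cfg = resources.files("infodem.data") / "demo_config.yaml"
    with resources.as_file(cfg) as p:
        a = run_pipeline(str(p), workdir / "run_a", seed=seed)
        b = run_pipeline(str(p), workdir / "run_b", seed=seed)
    ca, cb = _tree_checksums(a), _tree_checksums(b)
    return {"identical": ca == cb, "n_artifacts": len(ca), "checksums": ca}
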