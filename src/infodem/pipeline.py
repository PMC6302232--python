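"""End-to-end pipeline: simulate -> filter -> geolocate -> correct ->
topics -> themes -> prevalence -> report.

Each stage is a function over an output directory: it reads the
artifacts earlier stages wrote there and writes its own, so stages can
be re-run individually (and are exposed one-per-subcommand on the
CLI).  ``run_pipeline`` chains them and writes a JSON run manifest.
Re-running with the same config and seed reproduces byte-identical
CSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

import infodem
from infodem._util import ConfigurationError
from infodem.corpus import read_corpus, read_truth, write_corpus, write_truth
from infodem.correction import corrected_message_count, estimate_correction_factor, sample_for_annotation
from infodem.geo import Gazetteer, assignments_to_frame, default_exclusion_words, resolve_corpus_locations
from infodem.lexicon import Lexicon, filter_corpus, lexica_from_mapping, load_lexica, tokenize
from infodem.prevalence import county_prevalence, state_prevalence
from infodem.report import volume_share_table, volume_table
from infodem.synthetic import GeneratorConfig, claims_to_frame, county_boundaries, generate_claims, generate_corpus, generate_gazetteer
from infodem.themes import corpus_theme_loads, fit_themes, pmi_disease_theme, theme_given_disease
from infodem.topics import build_vocabulary, corpus_topic_loads, fit_lda, topic_disease_correlations

log = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "geolocate", "correct", "topics", "themes", "prevalence", "report"]


class PipelineConfig:
    """Validated top-level config for a full run."""

    def __init__(self, raw: Mapping, base_dir: Path | None = None):
        raw = dict(raw)
        self.seed = int(raw.get("seed", 0))
        gen = dict(raw.get("generator", {}))
        gen.setdefault("seed", self.seed)
        self.generator = GeneratorConfig.from_dict(gen)
        lex_path = raw.get("lexicon_path")
        if lex_path is not None:
            p = Path(lex_path)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            if not p.exists():
                raise ConfigurationError(f"lexicon_path {p} does not exist")
            self.lexica = load_lexica(p)
        else:
            self.lexica = lexica_from_mapping(self.generator.lexicon)
        self.lda = {"K": 10, "alpha": None, "beta": 0.01, "n_iter": 200, "burn_in": 80, "min_author_frac": 0.05}
        self.lda.update(raw.get("lda", {}))
        self.themes = {"T": 4, "n_iter": 400, "names": None}
        self.themes.update(raw.get("themes", {}))
        self.correction = {"sample_size": 30}
        self.correction.update(raw.get("correction", {}))
        pt = raw.get("prevalence_truth")
        if pt is not None:
            self.prevalence_truth = {
                (county, disease): float(p)
                for county, by_disease in pt.items()
                for disease, p in by_disease.items()
            }
        else:
            # deterministic planted prevalences in a plausible claims range
            rng = np.random.default_rng(self.seed + 2)
            self.prevalence_truth = {
                (c, d): float(np.round(rng.uniform(0.02, 0.30), 4))
                for c in self.generator.counties
                for d in self.generator.diseases
            }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh), base_dir=path.parent)


def _read_matched(outdir: Path):
    """(message_id -> matches) plus per-disease binary labels over matched ids."""
    rows = []
    with open(outdir / "matched.jsonl", encoding="utf-8") as fh:
        for line in fh:
            rows.append(json.loads(line))
    return rows


def _disease_labels(outdir: Path, all_ids: list[str], diseases: list[str]) -> pd.DataFrame:
    matched = _read_matched(outdir)
    labels = pd.DataFrame(0, index=pd.Index(all_ids, name="message_id"), columns=diseases, dtype=int)
    for row in matched:
        for d in {m[0] for m in row["matches"]}:
            labels.loc[row["message_id"], d] = 1
    return labels


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    pairs = list(generate_corpus(cfg.generator))
    write_corpus((m for m, _ in pairs), outdir / "corpus.jsonl")
    write_truth((t for _, t in pairs), outdir / "truth.jsonl")
    generate_gazetteer(cfg.generator).to_csv(outdir / "gazetteer.csv", index=False)
    claims = generate_claims(cfg.generator, cfg.prevalence_truth)
    claims_to_frame(claims).to_csv(outdir / "claims.csv", index=False)
    pd.DataFrame(
        [(c, d, p) for (c, d), p in sorted(cfg.prevalence_truth.items())],
        columns=["county", "disease", "prevalence"],
    ).to_csv(outdir / "prevalence_truth.csv", index=False)
    log.info("simulate: %d messages, %d claims", len(pairs), len(claims))


def stage_filter(cfg: PipelineConfig, outdir: Path) -> None:
    result = filter_corpus(read_corpus(outdir / "corpus.jsonl"), cfg.lexica)
    with open(outdir / "matched.jsonl", "w", encoding="utf-8") as fh:
        for mm in result.matched:
            fh.write(json.dumps(
                {"message_id": mm.message.message_id, "matches": [list(m) for m in mm.matches]},
                sort_keys=True,
            ) + "\n")
    result.keyword_table().to_csv(outdir / "keyword_counts.csv", index=False)
    result.disease_table().to_csv(outdir / "disease_counts.csv", index=False)
    log.info("filter: %d/%d messages matched", len(result.matched), result.n_input)


def stage_geolocate(cfg: PipelineConfig, outdir: Path) -> None:
    gaz = Gazetteer(pd.read_csv(outdir / "gazetteer.csv"), default_exclusion_words())
    assignments = resolve_corpus_locations(
        read_corpus(outdir / "corpus.jsonl"), gaz, county_boundaries(cfg.generator)
    )
    assignments_to_frame(assignments).to_csv(outdir / "county_assignments.csv", index=False)


def stage_correct(cfg: PipelineConfig, outdir: Path) -> None:
    from infodem.lexicon import MatchedMessage
    from infodem.corpus import Message

    truth = read_truth(outdir / "truth.jsonl")
    by_id = {m.message_id: m for m in read_corpus(outdir / "corpus.jsonl")}
    matched = [
        MatchedMessage(by_id[r["message_id"]], [tuple(m) for m in r["matches"]])
        for r in _read_matched(outdir)
    ]
    kw_counts = pd.read_csv(outdir / "keyword_counts.csv")
    dis_counts = pd.read_csv(outdir / "disease_counts.csv").set_index("disease")["messages"]
    ss = np.random.SeedSequence([cfg.seed, 101])
    factor_rows, corrected = [], []
    for lex in cfg.lexica:
        factors = {}
        counts = {}
        for kw, sub_seed in zip(lex.keywords, ss.spawn(len(lex.keywords))):
            n_k = int(kw_counts.query("disease == @lex.disease and keyword == @kw")["n_k"].sum())
            counts[kw] = n_k
            if n_k == 0:
                continue
            sample = sample_for_annotation(
                matched, kw, lex.disease, size=int(cfg.correction["sample_size"]),
                seed=int(sub_seed.generate_state(1)[0] & 0x7FFFFFFF), truth=truth,
            )
            cf = estimate_correction_factor(sample)
            factors[kw] = cf.w
            factor_rows.append((lex.disease, kw, n_k, cf.n_labeled, cf.w))
        corrected.append(
            corrected_message_count(lex.disease, factors, counts, raw_count=int(dis_counts.get(lex.disease, 0)))
        )
    pd.DataFrame(factor_rows, columns=["disease", "keyword", "n_k", "n_labeled", "w_k"]).to_csv(
        outdir / "correction_factors.csv", index=False
    )
    users = {
        lex.disease: len({mm.message.author_id for mm in matched if lex.disease in mm.diseases()})
        for lex in cfg.lexica
    }
    volume_table(corrected, users).to_csv(outdir / "volume_table.csv", index=False)


def stage_topics(cfg: PipelineConfig, outdir: Path) -> None:
    msgs = [(m.message_id, m.author_id, tokenize(m.text)) for m in read_corpus(outdir / "corpus.jsonl")]
    vocab = build_vocabulary(
        ((a, toks) for _, a, toks in msgs), cfg.lexica, float(cfg.lda["min_author_frac"])
    )
    model = fit_lda(
        [toks for _, _, toks in msgs], vocab,
        K=int(cfg.lda["K"]), alpha=cfg.lda["alpha"], beta=float(cfg.lda["beta"]),
        n_iter=int(cfg.lda["n_iter"]), burn_in=int(cfg.lda["burn_in"]), seed=cfg.seed,
    )
    model.save(outdir / "lda")
    loads = corpus_topic_loads(((mid, toks) for mid, _, toks in msgs), model)
    loads.to_csv(outdir / "topic_loads.csv")
    labels = _disease_labels(outdir, [mid for mid, _, _ in msgs], [l.disease for l in cfg.lexica])
    labels.to_csv(outdir / "disease_labels.csv")
    corr = topic_disease_correlations(loads, labels.loc[loads.index])
    corr.to_csv(outdir / "topic_correlations.csv", index=False)


def stage_themes(cfg: PipelineConfig, outdir: Path) -> None:
    import infodem.topics as topics_mod

    phi = np.load(outdir / "lda" / "phi.npy")
    prior = np.load(outdir / "lda" / "topic_prior.npy")
    meta = json.loads((outdir / "lda" / "model.json").read_text())
    tokens = pd.read_csv(outdir / "lda" / "vocabulary.csv")["token"].tolist()
    vocab = topics_mod.Vocabulary(tokens, {t: 1.0 for t in tokens}, 1)
    model = topics_mod.TopicModel(
        meta["K"], phi, prior, meta["alpha"], meta["beta"], vocab, meta["seed"], np.empty(0)
    )
    themes = fit_themes(
        model, T=int(cfg.themes["T"]), seed=cfg.seed,
        n_iter=int(cfg.themes["n_iter"]), names=cfg.themes["names"],
    )
    np.save(outdir / "theme_W.npy", themes.W)
    np.save(outdir / "theme_H.npy", themes.H)
    (outdir / "theme_names.yaml").write_text(yaml.safe_dump(themes.names))
    msgs = [(m.message_id, tokenize(m.text)) for m in read_corpus(outdir / "corpus.jsonl")]
    loads = corpus_theme_loads(msgs, themes, vocab.index)
    loads.to_csv(outdir / "theme_loads.csv")
    labels = pd.read_csv(outdir / "disease_labels.csv").set_index("message_id")
    stats = theme_given_disease(loads, labels, theme_names=themes.names)
    stats = pmi_disease_theme(stats)
    stats.to_csv(outdir / "theme_stats.csv", index=False)


def stage_prevalence(cfg: PipelineConfig, outdir: Path) -> None:
    claims = pd.read_csv(outdir / "claims.csv")
    table = county_prevalence(claims, cfg.generator.counties, cfg.generator.diseases)
    state = state_prevalence(table)
    table.county.to_csv(outdir / "prevalence_county.csv", index=False)
    state.to_csv(outdir / "prevalence_state.csv", index=False)


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    vol = pd.read_csv(outdir / "volume_table.csv")
    state = pd.read_csv(outdir / "prevalence_state.csv")
    from infodem.correction import CorrectedCount

    corrected = [
        CorrectedCount(r.disease, int(r.messages), float(r.corrected_count), int(r.corrected_count),
                       None if r.messages == 0 else r.corrected_count / r.messages)
        for r in vol.itertuples()
        if r.corrected_count > 0
    ]
    prev_counts = {
        r.disease: (int(r.pooled_patients), int(r.state_population)) for r in state.itertuples()
    }
    users = {r.disease: int(r.users) for r in vol.itertuples()}
    share = volume_share_table(corrected, prev_counts, users)
    share.to_csv(outdir / "volume_vs_prevalence.csv", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "geolocate": stage_geolocate,
    "correct": stage_correct,
    "topics": stage_topics,
    "themes": stage_themes,
    "prevalence": stage_prevalence,
    "report": stage_report,
}


def run_stage(name: str, cfg: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[name](cfg, outdir)


def run_pipeline(config: str | Path | Mapping, outdir: str | Path, seed: int | None = None) -> Path:
    """Run every stage in order and write a run manifest.

    ``seed`` overrides the config seed.  Configuration is validated
    before any artifact is written; a stage failure aborts with the
    stage name and a partial-output manifest.
    """
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
        base = Path(config).parent
    else:
        raw, base = dict(config), None
    if seed is not None:
        raw["seed"] = int(seed)
        raw.setdefault("generator", {})
        raw["generator"]["seed"] = int(seed)
    cfg = PipelineConfig(raw, base_dir=base)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": infodem.__version__,
        "seed": cfg.seed,
        "stages_completed": [],
        "artifacts": {},
    }
    try:
        for name in STAGES:
            _STAGE_FUNCS[name](cfg, outdir)
            manifest["stages_completed"].append(name)
    except Exception as exc:
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    for p in sorted(outdir.glob("*.csv")):
        manifest["artifacts"][p.name] = sum(1 for _ in open(p)) - 1
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
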