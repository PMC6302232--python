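"""Synthetic corpus, gazetteer, and claims generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* **Text** is drawn from a theme -> topic -> word hierarchy.  Theme-to-
  topic and topic-to-word distributions are Dirichlet draws; a message
  samples one theme, one topic from that theme, then its words from
  that topic.  LDA and NMF stages therefore have recoverable planted
  structure.
* **Keywords** are injected on top of the generated text.  Each
  injected use of keyword *k* is flagged *relevant* (a genuine disease
  reference) with the configured probability — the true per-keyword
  precision w_k.  Relevant uses bias the message's theme prior through
  ``disease_theme_bias``; irrelevant uses (the metaphorical "stroke"
  problem) land in messages drawn from the unbiased prior, so
  correction factors and content analyses interact realistically.
* **Authors** are fixed to a county (population-weighted); messages
  carry coordinates, a free-text location field, or nothing, per the
  configured ``geo_noise`` mix.
* **Claims** give each county resident at least one claim for a disease
  with the configured prevalence; duplicate claims per patient are
  generated so unique-patient de-duplication is exercised.

Everything is driven by one integer seed: the same config yields
byte-identical corpora, gazetteers, and claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from infodem._util import ConfigurationError
from infodem.corpus import ClaimRecord, Message, MessageTruth

SYNTH_STATE = "PA"
#: an always-ambiguous place name planted in every county's gazetteer
AMBIGUOUS_PLACE = "springview"
#: a fully concentrated place name that is also a common English word
EXCLUDED_PLACE = "park"


def _check_prob(value: float, name: str) -> float:
    if not (0.0 <= float(value) <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")
    return float(value)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world.

    Parameters
    ----------
    counties
        Ordered mapping of county name to resident population (>0).
    lexicon
        Disease name -> list of keyword phrases.  Defines both the
        disease list and the keywords available for injection.
    keyword_relevance
        Keyword phrase -> true probability that a use of the keyword
        refers to its disease (the planted w_k).
    disease_theme_bias
        Disease -> {theme index -> multiplicative weight} applied to
        the uniform theme prior for messages truly about that disease.
    keyword_rate
        Probability that a message carries one injected keyword use.
    geo_noise
        Fractions of messages carrying coordinates, a free-text
        location field, or nothing usable; must sum to 1.
    """

    n_users: int = 200
    n_messages: int = 2000
    counties: dict[str, int] = field(default_factory=lambda: {"alder": 5000, "birch": 5000, "cedar": 5000})
    lexicon: dict[str, list[str]] = field(
        default_factory=lambda: {"asthma": ["asthma"], "stroke": ["stroke"], "diabetes": ["diabetes"]}
    )
    keyword_relevance: dict[str, float] = field(
        default_factory=lambda: {"asthma": 0.95, "stroke": 0.15, "diabetes": 0.9}
    )
    n_themes: int = 4
    n_topics: int = 10
    vocab_size: int = 400
    theme_topic_conc: float = 0.2
    topic_word_conc: float = 0.1
    disease_theme_bias: dict[str, dict[int, float]] = field(default_factory=dict)
    keyword_rate: float = 0.35
    geo_noise: dict[str, float] = field(
        default_factory=lambda: {"coordinates": 0.5, "location_field": 0.4, "unmappable": 0.1}
    )
    msg_len_min: int = 5
    msg_len_max: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob(self.keyword_rate, "keyword_rate")
        for k, p in self.keyword_relevance.items():
            _check_prob(p, f"keyword_relevance[{k!r}]")
        for county, pop in self.counties.items():
            if pop <= 0:
                raise ConfigurationError(f"counties[{county!r}] population must be positive, got {pop}")
        for key in ("coordinates", "location_field", "unmappable"):
            if key not in self.geo_noise:
                raise ConfigurationError(f"geo_noise missing fraction {key!r}")
            _check_prob(self.geo_noise[key], f"geo_noise[{key!r}]")
        if abs(sum(self.geo_noise.values()) - 1.0) > 1e-9:
            raise ConfigurationError("geo_noise fractions must sum to 1")
        for d, biases in self.disease_theme_bias.items():
            if d not in self.lexicon:
                raise ConfigurationError(f"disease_theme_bias[{d!r}]: disease not in lexicon")
            for t, w in biases.items():
                if w < 0:
                    raise ConfigurationError(f"disease_theme_bias[{d!r}][{t}] must be >= 0, got {w}")
        if not (1 <= self.msg_len_min <= self.msg_len_max):
            raise ConfigurationError("message length bounds must satisfy 1 <= min <= max")
        for kw, disease in [(k, d) for d, kws in self.lexicon.items() for k in kws]:
            if kw not in self.keyword_relevance:
                raise ConfigurationError(f"keyword_relevance missing entry for keyword {kw!r} ({disease})")

    @property
    def diseases(self) -> list[str]:
        return list(self.lexicon)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "disease_theme_bias" in d:  # YAML keys arrive as strings
            d["disease_theme_bias"] = {
                dis: {int(t): float(w) for t, w in biases.items()} for dis, biases in d["disease_theme_bias"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _city_of(county: str) -> str:
    return county.replace(" ", "") + "ville"


def _county_cell(i: int) -> tuple[float, float]:
    """Lower-left corner of county i's 1x1-degree grid cell."""
    return -80.0 + (i % 10), 40.0 + 2.0 * (i // 10)


def county_boundaries(config: GeneratorConfig):
    """Rectangular boundary per county, as shapely geometries.

    Synthetic counties tile a lon/lat grid; real shapefiles can be
    substituted anywhere a boundary mapping is accepted.
    """
    from shapely.geometry import box

    out = {}
    for i, name in enumerate(config.counties):
        lon0, lat0 = _county_cell(i)
        out[name] = box(lon0, lat0, lon0 + 1.0, lat0 + 1.0)
    return out


def _hierarchy(config: GeneratorConfig, rng: np.random.Generator):
    theme_topic = rng.dirichlet([config.theme_topic_conc] * config.n_topics, size=config.n_themes)
    topic_word = rng.dirichlet([config.topic_word_conc] * config.vocab_size, size=config.n_topics)
    vocab = np.array([f"w{i:04d}" for i in range(config.vocab_size)])
    return theme_topic, topic_word, vocab


def _theme_prior(config: GeneratorConfig, disease: str | None) -> np.ndarray:
    prior = np.ones(config.n_themes)
    if disease is not None:
        for t, w in config.disease_theme_bias.get(disease, {}).items():
            prior[t] *= w
    return prior / prior.sum()


def generate_corpus(config: GeneratorConfig) -> Iterator[tuple[Message, MessageTruth]]:
    """Yield ``(message, truth)`` pairs; exactly ``n_messages`` of them."""
    rng = np.random.default_rng(config.seed)
    theme_topic, topic_word, vocab = _hierarchy(config, rng)
    county_names = list(config.counties)
    pops = np.array([config.counties[c] for c in county_names], dtype=float)
    author_county = rng.choice(len(county_names), size=config.n_users, p=pops / pops.sum())

    all_keywords = [(kw, d) for d, kws in config.lexicon.items() for kw in kws]
    geo_modes = ["coordinates", "location_field", "unmappable"]
    geo_p = np.array([config.geo_noise[m] for m in geo_modes])

    for i in range(config.n_messages):
        author = int(rng.integers(config.n_users))
        county_idx = int(author_county[author])
        county = county_names[county_idx]

        keyword_uses: list[tuple[str, bool]] = []
        disease: str | None = None
        if all_keywords and rng.random() < config.keyword_rate:
            kw, kw_disease = all_keywords[int(rng.integers(len(all_keywords)))]
            relevant = bool(rng.random() < config.keyword_relevance[kw])
            keyword_uses.append((kw, relevant))
            if relevant:
                disease = kw_disease

        theme = int(rng.choice(config.n_themes, p=_theme_prior(config, disease)))
        topic = int(rng.choice(config.n_topics, p=theme_topic[theme]))
        length = int(rng.integers(config.msg_len_min, config.msg_len_max + 1))
        words = list(vocab[rng.choice(config.vocab_size, size=length, p=topic_word[topic])])
        for kw, _ in keyword_uses:
            pos = int(rng.integers(len(words) + 1))
            words[pos:pos] = kw.split()
        text = " ".join(words)

        mode = geo_modes[int(rng.choice(3, p=geo_p))]
        lat = lon = None
        loc_field = None
        if mode == "coordinates":
            lon0, lat0 = _county_cell(county_idx)
            lon = round(float(lon0 + 0.1 + 0.8 * rng.random()), 6)
            lat = round(float(lat0 + 0.1 + 0.8 * rng.random()), 6)
        elif mode == "location_field":
            city = _city_of(county)
            loc_field = f"{city}, {SYNTH_STATE}" if rng.random() < 0.5 else city
        else:
            loc_field = AMBIGUOUS_PLACE if rng.random() < 0.5 else "planet earth"

        minutes = i % (60 * 24 * 365)
        ts = f"2014-01-01T00:00:00Z" if minutes == 0 else (
            pd.Timestamp("2014-01-01", tz="UTC") + pd.Timedelta(minutes=minutes)
        ).strftime("%Y-%m-%dT%H:%M:%SZ")

        msg = Message(
            message_id=f"m{i:07d}",
            author_id=f"u{author:05d}",
            timestamp=ts,
            text=text,
            latitude=lat,
            longitude=lon,
            location_field=loc_field,
        )
        truth = MessageTruth(
            message_id=msg.message_id,
            county=county,
            theme=theme,
            topic=topic,
            diseases=[disease] if disease else [],
            keyword_uses=keyword_uses,
        )
        yield msg, truth


def generate_gazetteer(config: GeneratorConfig, with_namesakes: bool = True) -> pd.DataFrame:
    """Place table (name, state, county, population) for the synthetic world.

    Each county gets one unambiguous city holding >=90% of its name's
    total population (a small out-of-state namesake tests the
    concentration rule); ``AMBIGUOUS_PLACE`` is split evenly across all
    counties so it can never be mapped; ``EXCLUDED_PLACE`` is fully
    concentrated but collides with a common English word.
    ``with_namesakes=False`` drops the out-of-state twins, leaving each
    city a single row with 100% of its name's population.
    """
    rows = []
    for county, pop in config.counties.items():
        city = _city_of(county)
        rows.append((city, SYNTH_STATE, county, int(pop)))
        if with_namesakes:
            rows.append((city, "ZZ", f"far {county}", max(1, int(pop) // 25)))  # ~4% namesake
    for i, (county, pop) in enumerate(config.counties.items()):
        state = SYNTH_STATE if i == 0 else f"S{i:02d}"  # namesakes spread across states
        rows.append((AMBIGUOUS_PLACE, state, county, max(1, int(pop) // 10)))
    first = next(iter(config.counties))
    rows.append((EXCLUDED_PLACE, SYNTH_STATE, first, 1000))
    return pd.DataFrame(rows, columns=["name", "state", "county", "population"])


def generate_claims(
    config: GeneratorConfig,
    prevalence_truth: Mapping[tuple[str, str], float],
    duplicate_rate: float = 0.3,
) -> list[ClaimRecord]:
    """Claims stream under planted per-(county, disease) prevalences.

    Each resident of county *c* acquires at least one claim for disease
    *d* with probability ``prevalence_truth[c, d]``; claimants then get
    extra duplicate rows at ``duplicate_rate`` (Poisson) so downstream
    unique-patient counting is exercised.
    """
    for (county, disease), p in prevalence_truth.items():
        if county not in config.counties:
            raise ConfigurationError(f"prevalence_truth county {county!r} not in configured counties")
        _check_prob(p, f"prevalence_truth[({county!r}, {disease!r})]")
    rng = np.random.default_rng(config.seed + 1)
    claims: list[ClaimRecord] = []
    for county, pop in config.counties.items():
        for disease in config.diseases:
            p = prevalence_truth.get((county, disease), 0.0)
            if p <= 0:
                continue
            n_pat = int(rng.binomial(pop, p)) if p < 1.0 else int(pop)
            patients = rng.choice(pop, size=n_pat, replace=False)
            for idx in np.sort(patients):
                n_rows = 1 + int(rng.poisson(duplicate_rate))
                claims.extend(ClaimRecord(f"{county}-{idx:06d}", county, disease) for _ in range(n_rows))
    return claims


def claims_to_frame(claims: list[ClaimRecord]) -> pd.DataFrame:
    return pd.DataFrame([(c.patient_id, c.county, c.disease) for c in claims], columns=["patient_id", "county", "disease"])
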