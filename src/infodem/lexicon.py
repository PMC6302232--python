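"""Keyword lexica, tokenization, and corpus filtering.

A lexicon maps one disease to a list of lowercase keyword phrases
(1-4 tokens).  Filtering keeps every message containing at least one
phrase match and tallies two side tables: per-keyword message counts
n_k (messages containing the keyword, not occurrences — the count the
corrected-volume formula consumes) and de-duplicated per-disease
message counts.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from infodem.corpus import Message

log = logging.getLogger(__name__)

URL_SENTINEL = "<url>"
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_TOKEN_RE = re.compile(r"<url>|[#@][\w']+|[\w']+")


def tokenize(text: str) -> list[str]:
    """Lowercased tokens; #hashtags/@mentions kept whole, URLs -> <url>.

    Unicode is NFKC-normalized first; punctuation is dropped except
    inside hashtags/mentions and word-internal apostrophes ("can't").
    """
    text = unicodedata.normalize("NFKC", text)
    text = _URL_RE.sub(f" {URL_SENTINEL} ", text)
    tokens = _TOKEN_RE.findall(text.lower())
    return [t for t in (tok.strip("'") if tok != URL_SENTINEL else tok for tok in tokens) if t]


@dataclass
class Lexicon:
    """Keyword phrases for one disease, stored pre-tokenized."""

    disease: str
    keywords: list[str]
    _phrases: list[tuple[str, tuple[str, ...]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"lexicon for {self.disease!r} has no keywords")
        if len(set(self.keywords)) != len(self.keywords):
            raise ValueError(f"lexicon for {self.disease!r} has duplicate keywords")
        self.keywords = [k.lower() for k in self.keywords]
        # longest phrase first so the scanner applies longest-match-wins;
        # original lexicon order breaks ties
        self._phrases = sorted(
            ((k, tuple(tokenize(k))) for k in self.keywords),
            key=lambda kt: -len(kt[1]),
        )

    def all_tokens(self) -> set[str]:
        return {tok for _, toks in self._phrases for tok in toks}


def load_lexica(path: str | Path) -> list[Lexicon]:
    """Load lexica from YAML ``{disease: [phrase, ...]}`` or CSV (disease, keyword)."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return [Lexicon(d, list(kws)) for d, kws in raw.items()]
    df = pd.read_csv(path)
    return [Lexicon(d, list(g["keyword"])) for d, g in df.groupby("disease", sort=False)]


def lexica_from_mapping(mapping: Mapping[str, list[str]]) -> list[Lexicon]:
    return [Lexicon(d, list(kws)) for d, kws in mapping.items()]


def default_lexica() -> list[Lexicon]:
    """The bundled 14-disease lexicon (editable stand-in; users may substitute their own)."""
    ref = resources.files("infodem.data") / "lexicon_default.yaml"
    with resources.as_file(ref) as p:
        return load_lexica(p)


def match_keywords(tokens: list[str], lexica: list[Lexicon]) -> list[tuple[str, str, int]]:
    """All maximal phrase matches as (disease, keyword, token offset).

    Per disease the scan is left-to-right with longest-phrase-wins, and
    a matched token run is consumed, so a run matches at most one
    keyword of that disease; diseases are matched independently.
    """
    matches: list[tuple[str, str, int]] = []
    n = len(tokens)
    for lex in lexica:
        i = 0
        while i < n:
            for keyword, phrase in lex._phrases:
                L = len(phrase)
                if L and tuple(tokens[i : i + L]) == phrase:
                    matches.append((lex.disease, keyword, i))
                    i += L
                    break
            else:
                i += 1
    return matches


@dataclass
class MatchedMessage:
    message: Message
    matches: list[tuple[str, str, int]]

    def diseases(self) -> set[str]:
        return {d for d, _, _ in self.matches}

    def keywords(self) -> set[tuple[str, str]]:
        return {(d, k) for d, k, _ in self.matches}


@dataclass
class FilterResult:
    """Filtered stream plus the count side tables."""

    matched: list[MatchedMessage]
    keyword_counts: dict[tuple[str, str], int]  # (disease, keyword) -> n_k
    disease_counts: dict[str, int]  # de-duplicated per-disease message count
    n_input: int
    n_skipped: int

    def keyword_table(self) -> pd.DataFrame:
        rows = [(d, k, n) for (d, k), n in sorted(self.keyword_counts.items())]
        return pd.DataFrame(rows, columns=["disease", "keyword", "n_k"])

    def disease_table(self) -> pd.DataFrame:
        rows = sorted(self.disease_counts.items())
        return pd.DataFrame(rows, columns=["disease", "messages"])


def _as_message(record) -> Message:
    if isinstance(record, Message):
        return record
    if isinstance(record, dict):
        return Message(**record)
    raise TypeError(f"unreadable corpus record of type {type(record).__name__}")


def filter_corpus(
    corpus: Iterable[Message],
    lexica: list[Lexicon],
    dedupe: bool = False,
) -> FilterResult:
    """Keep messages with >=1 keyword match and accumulate count tables.

    A message mentioning two diseases counts once toward each; n_k
    counts messages containing keyword k (multiple occurrences in one
    message count once).  Unreadable records are skipped with a logged
    warning.  ``dedupe`` collapses byte-identical texts (off by
    default: reposts are ordinarily kept).
    """
    keyword_counts: dict[tuple[str, str], int] = {
        (lex.disease, k): 0 for lex in lexica for k in lex.keywords
    }
    disease_counts: dict[str, int] = {lex.disease: 0 for lex in lexica}
    matched: list[MatchedMessage] = []
    seen_texts: set[str] = set()
    n_input = n_skipped = 0
    for record in corpus:
        n_input += 1
        try:
            msg = _as_message(record)
            tokens = tokenize(msg.text)
        except (TypeError, ValueError) as exc:
            log.warning("skipping unreadable corpus record: %s", exc)
            n_skipped += 1
            continue
        if dedupe:
            if msg.text in seen_texts:
                continue
            seen_texts.add(msg.text)
        hits = match_keywords(tokens, lexica)
        if not hits:
            continue
        mm = MatchedMessage(msg, hits)
        matched.append(mm)
        for d in mm.diseases():
            disease_counts[d] += 1
        for dk in mm.keywords():
            keyword_counts[dk] += 1
    return FilterResult(matched, keyword_counts, disease_counts, n_input, n_skipped)
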