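"""Per-keyword precision correction factors and corrected message counts.

Keyword filtering over-counts: many uses of ambiguous terms ("stroke",
"heart attack") are metaphorical or refer to other subjects.  A
correction factor w_k — the fraction of a 30-message annotated sample
containing keyword k that genuinely references the disease — scales
the per-keyword message count n_k, and the corrected disease count is

    corrected = sum_k w_k * n_k

over the disease's keywords.  Reported counts round half-up to
integers; internal arithmetic stays real-valued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from infodem._util import round_half_up
from infodem.corpus import MessageTruth
from infodem.lexicon import MatchedMessage

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZE = 30


class UndefinedFactorError(ValueError):
    """No labeled messages exist for the keyword; w_k is undefined."""


class MissingFactorError(KeyError):
    """A keyword with nonzero message count has no correction factor."""


@dataclass
class AnnotationSample:
    """A (<=30 by default) message sample for one keyword, with labels.

    ``labels[message_id]`` is True when the message genuinely
    references the disease.  In synthetic mode labels are auto-filled
    from the truth sidecar, standing in for manual review.
    """

    keyword: str
    disease: str
    message_ids: list[str]
    labels: dict[str, bool]

    def __post_init__(self) -> None:
        unlabeled = [m for m in self.message_ids if m not in self.labels]
        if unlabeled:
            raise ValueError(f"labels missing for sampled messages: {unlabeled[:5]}")


@dataclass(frozen=True)
class CorrectionFactor:
    keyword: str
    disease: str
    w: float  # estimated precision in [0, 1]
    n_labeled: int


@dataclass(frozen=True)
class CorrectedCount:
    disease: str
    raw_count: int
    corrected_real: float
    corrected_count: int  # half-up rounding of corrected_real
    aggregate_factor: float | None  # corrected_real / raw_count


def sample_for_annotation(
    matched: Iterable[MatchedMessage],
    keyword: str,
    disease: str,
    size: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
    truth: Mapping[str, MessageTruth] | None = None,
) -> AnnotationSample:
    """Uniform sample without replacement of messages containing the keyword.

    Fewer than ``size`` candidates -> take them all.  With a truth
    sidecar, each sampled message is auto-labeled relevant iff it has a
    relevant use of this keyword.
    """
    if size < 1:
        raise ValueError("sample size must be >= 1")
    candidates = sorted(
        {mm.message.message_id for mm in matched if (disease, keyword) in mm.keywords()}
    )
    if not candidates:
        log.warning("keyword %r (%s) has zero matching messages; factor undefined", keyword, disease)
        return AnnotationSample(keyword, disease, [], {})
    rng = np.random.default_rng(seed)
    if len(candidates) <= size:
        chosen = candidates
    else:
        chosen = sorted(rng.choice(candidates, size=size, replace=False).tolist())
    labels: dict[str, bool] = {}
    if truth is not None:
        for mid in chosen:
            uses = truth[mid].keyword_uses
            labels[mid] = any(k == keyword and rel for k, rel in uses)
    return AnnotationSample(keyword, disease, chosen, labels)


def estimate_correction_factor(sample: AnnotationSample) -> CorrectionFactor:
    """w_k = labeled-relevant / labeled, the sample precision of the keyword."""
    n = len(sample.message_ids)
    if n == 0:
        raise UndefinedFactorError(f"keyword {sample.keyword!r}: empty annotation sample")
    relevant = sum(bool(sample.labels[m]) for m in sample.message_ids)
    return CorrectionFactor(sample.keyword, sample.disease, relevant / n, n)


def corrected_message_count(
    disease: str,
    factors: Mapping[str, float],
    counts: Mapping[str, int],
    raw_count: int | None = None,
) -> CorrectedCount:
    """Apply corrected = sum_k w_k * n_k over the disease's keywords.

    ``raw_count`` is the de-duplicated disease message count used for
    the reported aggregate factor; it defaults to sum(n_k).  A message
    holding two keywords of the same disease enters both n_k terms, so
    the corrected count can exceed the de-duplicated raw count in
    pathological lexica (warned, not an error).
    """
    missing = sorted(k for k, n in counts.items() if n > 0 and k not in factors)
    if missing:
        raise MissingFactorError(f"no correction factor for keywords with messages: {missing}")
    corrected_real = float(sum(factors[k] * n for k, n in counts.items() if n > 0))
    raw = int(raw_count) if raw_count is not None else int(sum(counts.values()))
    if raw and corrected_real > raw:
        log.warning(
            "%s: corrected count %.1f exceeds de-duplicated raw count %d "
            "(overlapping keywords of one disease)", disease, corrected_real, raw
        )
    return CorrectedCount(
        disease=disease,
        raw_count=raw,
        corrected_real=corrected_real,
        corrected_count=int(round_half_up(corrected_real)),
        aggregate_factor=(corrected_real / raw) if raw else None,
    )


def write_annotation_csv(sample: AnnotationSample, texts: Mapping[str, str], path: str | Path) -> None:
    """Exchange format for real manual review: keyword, message_id, text, label."""
    rows = [
        (sample.keyword, mid, texts.get(mid, ""), int(sample.labels[mid]) if mid in sample.labels else "")
        for mid in sample.message_ids
    ]
    pd.DataFrame(rows, columns=["keyword", "message_id", "text", "label"]).to_csv(path, index=False)


def read_annotation_csv(path: str | Path, disease: str) -> AnnotationSample:
    df = pd.read_csv(path, dtype={"label": "Int64"})
    keyword = str(df["keyword"].iloc[0])
    ids = [str(m) for m in df["message_id"]]
    labels = {str(m): bool(l) for m, l in zip(df["message_id"], df["label"]) if pd.notna(l)}
    return AnnotationSample(keyword, disease, ids, labels)
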