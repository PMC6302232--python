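"""Summary tables: corrected-volume shares vs. prevalence shares.

Every percentage in a report is recomputed from the emitted count
tables — reports carry no free-floating numbers.  Percentages round
half-up to 2 decimals, corrected counts half-up to integers.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from infodem._util import pct
from infodem.correction import CorrectedCount

log = logging.getLogger(__name__)


def volume_share_table(
    corrected: Sequence[CorrectedCount],
    prevalence_counts: Mapping[str, tuple[int, int]] | None = None,
    users: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Disease share of total corrected message volume, beside prevalence share.

    ``prevalence_counts`` maps disease -> (pooled unique patients,
    state population).  Diseases missing on either side are excluded
    with a warning.
    """
    rows = {c.disease: c for c in corrected}
    diseases = list(rows)
    if prevalence_counts is not None:
        missing = sorted(set(diseases) ^ set(prevalence_counts))
        if missing:
            log.warning("diseases present on only one side are excluded: %s", missing)
            diseases = [d for d in diseases if d in prevalence_counts]
    total = sum(rows[d].corrected_count for d in diseases)
    if total <= 0:
        raise ValueError("total corrected message count is zero")
    records = []
    for d in diseases:
        c = rows[d]
        rec = {
            "disease": d,
            "corrected_count": c.corrected_count,
            "message_share_pct": pct(c.corrected_count, total),
        }
        if users is not None:
            rec["users"] = users.get(d)
        if prevalence_counts is not None:
            patients, population = prevalence_counts[d]
            rec["patients"] = patients
            rec["prevalence_share_pct"] = pct(patients, population)
        records.append(rec)
    return pd.DataFrame(records)


def nonreference_share(raw: int, relevant: float) -> float | None:
    """(raw - relevant)/raw as a percentage to 2 decimals; None when raw = 0."""
    if raw < 0 or relevant < 0 or relevant > raw:
        raise ValueError("need 0 <= relevant <= raw")
    if raw == 0:
        return None
    return pct(raw - relevant, raw)


def volume_table(
    corrected: Sequence[CorrectedCount],
    users: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-disease volume table: raw count, correction factor %, corrected count, users."""
    records = []
    for c in corrected:
        rec = {
            "disease": c.disease,
            "messages": c.raw_count,
            "correction_factor_pct": (
                pct(c.corrected_real, c.raw_count, 1) if c.raw_count else None
            ),
            "corrected_count": c.corrected_count,
        }
        if users is not None:
            rec["users"] = users.get(c.disease)
        records.append(rec)
    return pd.DataFrame(records)
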