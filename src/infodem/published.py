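"""Bundled published statewide summary tables and their derived figures.

Three small tables from a published statewide Twitter/claims
surveillance study ship with the package: the per-disease volume table
(raw counts, correction factors, corrected counts, users), pooled
unique-patient counts for the five diseases with printed claims
figures, and per-theme message counts for the printed theme examples.
They serve as worked-example inputs: every published proportion can be
recomputed from them with the package's own operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("infodem.data") / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def published_volume_table() -> pd.DataFrame:
    """disease, messages, correction_factor_pct, corrected_count, users."""
    return _read("published_volume_table.csv")


def published_prevalence_counts() -> pd.DataFrame:
    """disease, pooled unique patients, state population."""
    return _read("published_prevalence_counts.csv")


def published_theme_counts() -> pd.DataFrame:
    """disease, theme, theme message count, disease message total."""
    return _read("published_theme_counts.csv")
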