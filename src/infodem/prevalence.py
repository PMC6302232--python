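"""Claims-based disease prevalence per county and statewide.

Prevalence for (county, disease) is the number of *unique* patients in
the county holding at least one claim for the disease, divided by the
county population.  Two state-level summaries are always reported,
because both appear in practice: the unweighted mean of county
prevalences, and the pooled share (statewide unique patients over
statewide population) that headline percentages use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from infodem.corpus import ClaimRecord


@dataclass
class PrevalenceTable:
    county: pd.DataFrame  # county, disease, patients, population, prevalence
    state: pd.DataFrame | None = None  # disease, mean_prevalence, pooled_patients, state_population, pooled_share


def _claims_frame(claims) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        df = claims[["patient_id", "county", "disease"]].copy()
    else:
        df = pd.DataFrame(
            [(c.patient_id, c.county, c.disease) for c in claims],
            columns=["patient_id", "county", "disease"],
        )
    return df


def county_prevalence(
    claims: Iterable[ClaimRecord] | pd.DataFrame,
    populations: Mapping[str, int],
    diseases: Sequence[str] | None = None,
) -> PrevalenceTable:
    """Unique-patient prevalence per (county, disease).

    Every configured county appears for every disease (zero-filled),
    so the state mean is over all counties.  Claims naming a county
    without a population are a hard error.
    """
    df = _claims_frame(claims)
    unknown = sorted(set(df["county"]) - set(populations))
    if unknown:
        raise ValueError(f"claims reference counties with no population: {unknown}")
    if diseases is None:
        diseases = sorted(df["disease"].unique())
    unique = df.drop_duplicates(["patient_id", "disease", "county"])
    counts = unique.groupby(["county", "disease"]).size()
    idx = pd.MultiIndex.from_product([sorted(populations), list(diseases)], names=["county", "disease"])
    table = counts.reindex(idx, fill_value=0).rename("patients").reset_index()
    table["population"] = [populations[c] for c in table["county"]]
    table["prevalence"] = table["patients"] / table["population"]
    return PrevalenceTable(county=table)


def state_prevalence(table: PrevalenceTable) -> pd.DataFrame:
    """Per-disease state summaries: unweighted county mean and pooled share."""
    df = table.county
    if df.empty:
        raise ValueError("county prevalence table is empty")
    out = (
        df.groupby("disease")
        .agg(mean_prevalence=("prevalence", "mean"), pooled_patients=("patients", "sum"))
        .reset_index()
    )
    state_pop = int(df.drop_duplicates("county")["population"].sum())
    out["state_population"] = state_pop
    out["pooled_share"] = out["pooled_patients"] / state_pop
    table.state = out
    return out
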