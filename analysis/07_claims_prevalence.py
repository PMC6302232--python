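"""Compute unique-patient disease prevalence per county from the demo
claims, plus both state summaries (unweighted county mean and pooled
share) compared against the planted prevalence truth."""

from pathlib import Path

import pandas as pd
from helpers import load_demo_config

from infodem.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("prevalence", cfg, OUT)
    state = pd.read_csv(OUT / "prevalence_state.csv")
    truth = pd.read_csv(OUT / "prevalence_truth.csv")
    planted_mean = truth.groupby("disease")["prevalence"].mean().rename("planted_county_mean")
    merged = state.merge(planted_mean, on="disease")
    print("state prevalence summaries vs planted truth:")
    print(merged[["disease", "mean_prevalence", "pooled_share", "planted_county_mean"]]
          .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
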