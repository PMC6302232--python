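"""Cluster the 10 LDA topics into 4 themes by NMF, assign per-message
theme distributions, and compute p(theme|disease) and disease-theme PMI."""

from pathlib import Path

import pandas as pd
from helpers import load_demo_config

from infodem.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("themes", cfg, OUT)
    stats = pd.read_csv(OUT / "theme_stats.csv")
    print("p(theme | disease) and PMI per (disease, theme):")
    print(stats.to_string(index=False))
    best = stats.loc[stats.groupby("disease")["pmi"].idxmax()]
    print("\nmost over-represented theme per disease (max PMI):")
    print(best[["disease", "theme_name", "p_pct", "pmi"]].to_string(index=False))


if __name__ == "__main__":
    main()
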