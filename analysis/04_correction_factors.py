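"""Estimate per-keyword precision correction factors w_k from 30-message
auto-annotated samples and compute corrected disease message counts
(sum of w_k * n_k)."""

from pathlib import Path

import pandas as pd
from helpers import load_demo_config

from infodem.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("correct", cfg, OUT)
    factors = pd.read_csv(OUT / "correction_factors.csv")
    vol = pd.read_csv(OUT / "volume_table.csv")
    print("per-keyword correction factors:")
    print(factors.to_string(index=False))
    print("\nvolume table (raw count, aggregate factor %, corrected count, users):")
    print(vol.to_string(index=False))
    planted = {k: v for k, v in cfg.generator.keyword_relevance.items()}
    print(f"\nplanted keyword precisions for comparison: {planted}")


if __name__ == "__main__":
    main()
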