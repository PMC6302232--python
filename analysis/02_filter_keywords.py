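"""Filter the demo corpus against the disease keyword lexica and tally
per-keyword (n_k) and de-duplicated per-disease message counts."""

from pathlib import Path

import pandas as pd
from helpers import load_demo_config

from infodem.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("filter", cfg, OUT)
    kw = pd.read_csv(OUT / "keyword_counts.csv")
    dis = pd.read_csv(OUT / "disease_counts.csv")
    print("per-keyword message counts n_k:")
    print(kw.to_string(index=False))
    print("\nde-duplicated per-disease counts:")
    print(dis.to_string(index=False))
    print(f"\n{dis['messages'].sum()} disease-message pairs from the 2,000-message corpus")


if __name__ == "__main__":
    main()
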