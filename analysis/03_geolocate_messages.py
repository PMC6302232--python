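"""Assign each demo message a county (coordinates first, then the
free-text location field under the 90% concentration rule) and score
accuracy against the ground-truth sidecar."""

from pathlib import Path

import pandas as pd
from helpers import load_demo_config

from infodem.corpus import read_truth
from infodem.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("geolocate", cfg, OUT)
    asg = pd.read_csv(OUT / "county_assignments.csv", keep_default_na=False)
    truth = read_truth(OUT / "truth.jsonl")
    print("assignment method tally:")
    print(asg["method"].value_counts().to_string())
    mapped = asg[asg["method"] != "unmapped"]
    correct = sum(truth[r.message_id].county == r.county for r in mapped.itertuples())
    print(f"\n{correct}/{len(mapped)} mapped messages assigned to their true county "
          f"({100 * correct / len(mapped):.1f}%)")


if __name__ == "__main__":
    main()
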