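"""Final report: corrected message-volume share per disease beside its
pooled claims-prevalence share (the over/under-representation
comparison), plus the same computation on the bundled published
statewide tables."""

from pathlib import Path

import pandas as pd
from helpers import load_demo_config

from infodem.correction import CorrectedCount
from infodem.pipeline import run_stage
from infodem.published import published_prevalence_counts, published_volume_table
from infodem.report import volume_share_table

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("report", cfg, OUT)
    print("demo corpus: volume share vs prevalence share")
    print(pd.read_csv(OUT / "volume_vs_prevalence.csv").to_string(index=False))

    vol = published_volume_table()
    corrected = [
        CorrectedCount(r.disease, int(r.messages), float(r.corrected_count), int(r.corrected_count), None)
        for r in vol.itertuples()
    ]
    shares = volume_share_table(corrected).set_index("disease")
    prev = published_prevalence_counts().set_index("disease")
    print("\npublished statewide tables, shares recomputed by the same operations:")
    print(f"  total raw messages      {vol['messages'].sum():>9,}")
    print(f"  total corrected         {vol['corrected_count'].sum():>9,}")
    for d in prev.index:
        msg = shares.loc[d, "message_share_pct"]
        ps = 100 * prev.loc[d, "patients"] / prev.loc[d, "state_population"]
        tag = "over" if msg > ps else "under"
        print(f"  {d:<14} volume {msg:>6.2f}%  prevalence {ps:>6.2f}%  -> {tag}-represented")


if __name__ == "__main__":
    main()
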