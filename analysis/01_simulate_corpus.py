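"""Generate the demo synthetic world: 2,000 messages from 300 authors
across 4 counties, with a gazetteer and claims records, all with
ground-truth sidecars.  Writes results/demo_run/{corpus,truth}.jsonl,
gazetteer.csv, claims.csv, prevalence_truth.csv."""

from pathlib import Path

from helpers import load_demo_config

from infodem.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "demo_run"


def main() -> None:
    cfg = load_demo_config()
    run_stage("simulate", cfg, OUT)
    n_msgs = sum(1 for _ in open(OUT / "corpus.jsonl"))
    n_claims = sum(1 for _ in open(OUT / "claims.csv")) - 1
    print(f"simulated {n_msgs} messages and {n_claims} claim rows into {OUT}")
    print(f"counties: {list(cfg.generator.counties)}; diseases: {cfg.generator.diseases}")


if __name__ == "__main__":
    main()
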