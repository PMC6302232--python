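"""Shared plumbing for the numbered analysis drivers."""

from importlib import resources

import yaml

from infodem.pipeline import PipelineConfig


def load_demo_config(seed: int | None = None) -> PipelineConfig:
    ref = resources.files("infodem.data") / "demo_config.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if seed is not None:
        raw["seed"] = seed
        raw.setdefault("generator", {})["seed"] = seed
    return PipelineConfig(raw)
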