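"""Message, truth-sidecar, and claim record types with JSON-lines IO.

A corpus is a JSON-lines file with one :class:`Message` per line.
Ground truth for synthetic corpora travels in a *sidecar* stream keyed
by ``message_id`` rather than inside the message itself, so downstream
filtering and modelling stages cannot see it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Message:
    """One social-media post.

    ``latitude``/``longitude`` are decimal degrees and must be present
    together; ``location_field`` is the free-text self-reported location
    from the author's profile.
    """

    message_id: str
    author_id: str
    timestamp: str
    text: str
    latitude: float | None = None
    longitude: float | None = None
    location_field: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("message text must be non-empty")
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError("latitude and longitude must be present together")

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return json.dumps(d, sort_keys=True, ensure_ascii=False)

    @classmethod
    def from_json(cls, line: str) -> "Message":
        return cls(**json.loads(line))


@dataclass(frozen=True)
class MessageTruth:
    """Ground truth for one synthetic message.

    ``keyword_uses`` lists ``[keyword, relevant]`` pairs: each injected
    keyword occurrence flagged by whether it truly refers to its
    disease.  ``diseases`` lists the diseases the message is genuinely
    about (relevant uses only).
    """

    message_id: str
    county: str
    theme: int
    topic: int
    diseases: list[str] = field(default_factory=list)
    keyword_uses: list[tuple[str, bool]] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["keyword_uses"] = [[k, bool(r)] for k, r in self.keyword_uses]
        return json.dumps(d, sort_keys=True, ensure_ascii=False)

    @classmethod
    def from_json(cls, line: str) -> "MessageTruth":
        d = json.loads(line)
        d["keyword_uses"] = [(k, bool(r)) for k, r in d.get("keyword_uses", [])]
        return cls(**d)


@dataclass(frozen=True)
class ClaimRecord:
    """One health-care claim row: a patient, their county, a disease."""

    patient_id: str
    county: str
    disease: str


def write_corpus(messages: Iterable[Message], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for m in messages:
            fh.write(m.to_json() + "\n")
            n += 1
    return n


def read_corpus(path: str | Path) -> Iterator[Message]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Message.from_json(line)


def write_truth(truths: Iterable[MessageTruth], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for t in truths:
            fh.write(t.to_json() + "\n")
            n += 1
    return n


def read_truth(path: str | Path) -> dict[str, MessageTruth]:
    out: dict[str, MessageTruth] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                t = MessageTruth.from_json(line)
                out[t.message_id] = t
    return out
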