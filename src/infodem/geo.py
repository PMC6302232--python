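"""County assignment from coordinates or free-text location fields.

Coordinates are resolved by point-in-region lookup against a boundary
mapping (county name -> shapely geometry).  Free-text locations are
resolved against a gazetteer of (place name, state, county,
population) rows: an explicit "city, state" is looked up directly; a
bare city name maps only when one place holds at least 90% of the
total population across all same-named places and the name is not a
common English/Spanish word (the exclusion list); bare county names
follow the same concentration rule.
"""

from __future__ import annotations

import logging
import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from infodem.corpus import Message

log = logging.getLogger(__name__)

METHOD_COORDINATES = "coordinates"
METHOD_CITY = "city_rule"
METHOD_COUNTY = "county_rule"
METHOD_UNMAPPED = "unmapped"

_CLEAN_RE = re.compile(r"[^a-z0-9,\s']+")


def _normalize(location: str) -> str:
    text = unicodedata.normalize("NFKC", location).casefold()
    text = _CLEAN_RE.sub(" ", text)
    return re.sub(r"\s+", " ", text).strip()


def default_exclusion_words() -> frozenset[str]:
    """Bundled common-word list (editable stand-in for top-1000 noun/verb/adjective lists)."""
    ref = resources.files("infodem.data") / "exclusion_words.txt"
    words = [
        w
        for line in ref.read_text(encoding="utf-8").splitlines()
        if not line.lstrip().startswith("#")
        for w in line.split()
    ]
    return frozenset(w.casefold() for w in words)


class Gazetteer:
    """Place table plus the common-word exclusion list.

    (name, state) pairs must be unique; populations nonnegative.
    """

    def __init__(self, places: pd.DataFrame, exclusion: Iterable[str] = ()):
        required = {"name", "state", "county", "population"}
        if not required.issubset(places.columns):
            raise ValueError(f"gazetteer needs columns {sorted(required)}")
        df = places.copy()
        for col in ("name", "state", "county"):
            df[col] = df[col].astype(str).str.strip().str.casefold()
        if (df["population"] < 0).any():
            raise ValueError("gazetteer populations must be >= 0")
        if df.duplicated(["name", "state"]).any():
            dupes = df[df.duplicated(["name", "state"], keep=False)]
            raise ValueError(f"duplicate (name, state) rows in gazetteer: {sorted(set(dupes['name']))}")
        self.places = df
        self.exclusion = frozenset(w.casefold() for w in exclusion)
        self._by_name = {name: g for name, g in df.groupby("name")}
        self._by_name_state = {(r["name"], r["state"]): r["county"] for _, r in df.iterrows()}
        # county populations aggregated from place rows, for bare county names
        cpop = df.groupby(["county", "state"], as_index=False)["population"].sum()
        self._county_rows = {name: g for name, g in cpop.groupby(cpop["county"].str.removesuffix(" county"))}

    @classmethod
    def from_csv(cls, path: str | Path, exclusion_path: str | Path | None = None) -> "Gazetteer":
        places = pd.read_csv(path)
        if exclusion_path is None:
            exclusion = default_exclusion_words()
        else:
            exclusion = [
                w
                for line in Path(exclusion_path).read_text(encoding="utf-8").splitlines()
                if not line.lstrip().startswith("#")
                for w in line.split()
            ]
        return cls(places, exclusion)


@dataclass(frozen=True)
class CountyAssignment:
    """County (or None) for one message, with the rule that produced it."""

    message_id: str
    county: str | None
    method: str

    def __post_init__(self) -> None:
        if (self.county is None) != (self.method == METHOD_UNMAPPED):
            raise ValueError("county must be None exactly when method is 'unmapped'")


def county_from_coordinates(lat: float, lon: float, boundaries: Mapping[str, object]) -> str | None:
    """Point-in-region lookup; None when outside every boundary."""
    from shapely.geometry import Point

    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError(f"coordinates must be finite, got lat={lat}, lon={lon}")
    pt = Point(lon, lat)
    for county in sorted(boundaries):
        if boundaries[county].covers(pt):
            return county
    return None


def _concentrated(group: pd.DataFrame, threshold: float) -> str | None:
    total = group["population"].sum()
    if total <= 0:
        return None
    best = group.loc[group["population"].idxmax()]
    if best["population"] / total >= threshold:
        return str(best["county"])
    return None


def county_from_location_field(
    location: str,
    gazetteer: Gazetteer,
    threshold: float = 0.90,
) -> tuple[str | None, str]:
    """Resolve a free-text location to (county, method).

    Returns (None, 'unmapped') when no rule applies; never raises on
    messy input.
    """
    text = _normalize(location or "")
    if not text:
        return None, METHOD_UNMAPPED
    parts = [p.strip() for p in text.split(",") if p.strip()]
    if len(parts) >= 2:
        county = gazetteer._by_name_state.get((parts[0], parts[1]))
        if county is not None:
            return county, METHOD_CITY
    name = parts[0]
    if name not in gazetteer.exclusion:
        group = gazetteer._by_name.get(name)
        if group is not None:
            county = _concentrated(group, threshold)
            if county is not None:
                return county, METHOD_CITY
        cgroup = gazetteer._county_rows.get(name.removesuffix(" county"))
        if cgroup is not None:
            county = _concentrated(cgroup, threshold)
            if county is not None:
                return county, METHOD_COUNTY
    return None, METHOD_UNMAPPED


def resolve_corpus_locations(
    corpus: Iterable[Message],
    gazetteer: Gazetteer,
    boundaries: Mapping[str, object],
    threshold: float = 0.90,
) -> list[CountyAssignment]:
    """One assignment per message; coordinates take priority over the location field."""
    out: list[CountyAssignment] = []
    tally: Counter[str] = Counter()
    for msg in corpus:
        county: str | None = None
        method = METHOD_UNMAPPED
        if msg.latitude is not None and msg.longitude is not None:
            county = county_from_coordinates(msg.latitude, msg.longitude, boundaries)
            if county is not None:
                method = METHOD_COORDINATES
        if county is None and msg.location_field:
            county, method = county_from_location_field(msg.location_field, gazetteer, threshold)
        out.append(CountyAssignment(msg.message_id, county, method))
        tally[method] += 1
    log.info("county assignment methods: %s", dict(tally))
    return out


def assignments_to_frame(assignments: list[CountyAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.message_id, a.county if a.county is not None else "", a.method) for a in assignments],
        columns=["message_id", "county", "method"],
    )
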