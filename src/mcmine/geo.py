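"""Location recognition: per-second GPS fixes resolved against personal maps.

Instead of reverse geocoding against a commercial map service, each user
carries a personal map of named places (Home, Office, Restaurant, Gym,
Mall) with a centre coordinate and a radius; a fix resolves to the nearest
place whose great-circle distance is within that radius, or ``Unknown``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .contexts import LOCATIONS, UNKNOWN_PLACE

EARTH_RADIUS_M = 6371008.8  # mean Earth radius
DEFAULT_RADIUS_M = 50.0

#: a gap in fixes longer than this finalizes the open location context
GPS_DROPOUT_S = 5.0


@dataclass(frozen=True)
class GpsFix:
    t: float
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")


@dataclass(frozen=True)
class PersonalPlace:
    label: str
    lat: float
    lon: float
    radius_m: float = DEFAULT_RADIUS_M

    def __post_init__(self) -> None:
        if self.label not in LOCATIONS:
            raise ValueError(f"unknown place label {self.label!r}")
        if self.radius_m <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PersonalMap:
    user_id: str
    places: tuple[PersonalPlace, ...]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.places]
        if len(set(labels)) != len(labels):
            raise ValueError("place labels must be unique per user")


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres between two (lat, lon) pairs."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def resolve_place(fix: GpsFix, pmap: PersonalMap) -> str:
    """Nearest in-radius place label, or ``Unknown``.

    Ties (equal distances) break lexicographically on the label.
    """
    if not pmap.places:
        raise ValueError("personal map is empty")
    best: Optional[tuple[float, str]] = None
    for place in pmap.places:
        d = haversine_m(fix.lat, fix.lon, place.lat, place.lon)
        if d <= place.radius_m:
            key = (d, place.label)
            if best is None or key < best:
                best = key
    return best[1] if best is not None else UNKNOWN_PLACE


def build_map(user_id: str, entries: Sequence[dict]) -> PersonalMap:
    """Validated personal map from {label, lat, lon, radius_m} entries."""
    places = tuple(
        PersonalPlace(
            label=e["label"], lat=float(e["lat"]), lon=float(e["lon"]),
            radius_m=float(e.get("radius_m", DEFAULT_RADIUS_M)),
        )
        for e in entries
    )
    return PersonalMap(user_id=user_id, places=places)


def load_map(path: Union[str, Path]) -> PersonalMap:
    with open(path) as fh:
        raw = json.load(fh)
    return build_map(raw["user"], raw["places"])


def save_map(pmap: PersonalMap, path: Union[str, Path]) -> None:
    raw = {"user": pmap.user_id, "places": [
        {"label": p.label, "lat": p.lat, "lon": p.lon, "radius_m": p.radius_m}
        for p in pmap.places
    ]}
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


class GeoLocationRecognizer:
    """Fix-in, label-out facade; needs no training."""

    recognizer_id = "geo_location"
    category = "location"

    def __init__(self, pmap: PersonalMap) -> None:
        self.pmap = pmap

    def predict_fix(self, fix: GpsFix) -> str:
        return resolve_place(fix, self.pmap)
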