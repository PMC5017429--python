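"""Shared context vocabulary and the definitional high-level context model.

Low-level contexts (LLCs) are atomic recognized states — a physical
activity, an emotion or a location — each carrying a user, a label and a
half-open time interval ``[t_start, t_end)`` (``t_end is None`` means the
context is still open).  A high-level context (HLC) is an abstract state
such as *OfficeWork* defined over a set of concurrent LLCs, at most one
per category.

Classification of an HLC is definitional: each :class:`HlcDefinition`
states which activities are required and which locations / emotions are
allowed (``ANY`` accepts anything, including an absent category).  The
highest-priority matching definition names the class; if none matches the
instance stays ``Unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Label vocabulary
# ---------------------------------------------------------------------------

ACTIVITIES: tuple[str, ...] = (
    "Eating", "Running", "Sitting", "Standing",
    "Walking", "Stretching", "Sweeping", "LyingDown",
)
EMOTIONS: tuple[str, ...] = ("Anger", "Happiness", "Neutral", "Sadness")
LOCATIONS: tuple[str, ...] = ("Home", "Office", "Restaurant", "Gym", "Mall")
HLC_CLASSES: tuple[str, ...] = (
    "Inactivity", "OfficeWork", "Exercising", "HavingMeal", "Housework",
)

#: activities observable by the skeleton (video) recognizer — everything but
#: the two ambulatory classes, which are seldom performed in front of a
#: stationary depth camera.
INDOOR_ACTIVITIES: tuple[str, ...] = tuple(
    a for a in ACTIVITIES if a not in ("Walking", "Running")
)

CATEGORIES: tuple[str, ...] = ("activity", "emotion", "location")

LABELS_BY_CATEGORY: dict[str, tuple[str, ...]] = {
    "activity": ACTIVITIES,
    "emotion": EMOTIONS,
    "location": LOCATIONS,
}

UNCLASSIFIED = "Unclassified"
UNKNOWN_PLACE = "Unknown"

MODALITIES: tuple[str, ...] = ("inertial", "skeleton", "audio", "gps")


class _Any:
    """Singleton wildcard used in definitions for 'any label, or absent'."""

    _instance: Optional["_Any"] = None

    def __new__(cls) -> "_Any":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "ANY"


ANY = _Any()


# ---------------------------------------------------------------------------
# Instances
# ---------------------------------------------------------------------------

@dataclass
class SensoryPacket:
    """A unit of raw sensory data: samples plus routing metadata."""

    user_id: str
    modality: str
    t_start: float
    sampling_rate: float
    samples: np.ndarray  # (n_samples, n_channels)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.shape[0] < 1:
            raise ValueError("packet must contain at least one sample")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


def interval_contains(t_start: float, t_end: Optional[float], t: float) -> bool:
    """Half-open containment: ``t_start <= t < t_end`` (open end = no bound)."""
    return t >= t_start and (t_end is None or t < t_end)


@dataclass(frozen=True)
class LowLevelContext:
    user_id: str
    category: str
    label: str
    t_start: float
    t_end: Optional[float] = None  # None = still open

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.label not in LABELS_BY_CATEGORY[self.category]:
            raise ValueError(
                f"label {self.label!r} not legal for category {self.category!r}"
            )
        if self.t_end is not None and self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    def contains(self, t: float) -> bool:
        return interval_contains(self.t_start, self.t_end, t)


@dataclass
class HighLevelContext:
    user_id: str
    constituents: tuple[LowLevelContext, ...]
    t_start: float
    t_end: Optional[float] = None
    hlc_class: str = UNCLASSIFIED

    def constituent(self, category: str) -> Optional[LowLevelContext]:
        for llc in self.constituents:
            if llc.category == category:
                return llc
        return None

    @property
    def labels(self) -> dict[str, str]:
        return {c.category: c.label for c in self.constituents}


# ---------------------------------------------------------------------------
# Definitions
# ---------------------------------------------------------------------------

AllowedSet = Union[_Any, frozenset]


@dataclass(frozen=True)
class HlcDefinition:
    """One definitional rule: required activities, allowed locations/emotions.

    ``priority`` is a unique integer rank; rank 1 is checked first.  By
    convention more specific definitions (fewer ``ANY`` fields) get better
    ranks, so e.g. *OfficeWork* (Sitting at the Office) wins over the
    catch-all *Inactivity* (Sitting anywhere).
    """

    hlc_class: str
    required_activities: frozenset
    allowed_locations: AllowedSet
    allowed_emotions: AllowedSet
    priority: int

    def __post_init__(self) -> None:
        if self.hlc_class not in HLC_CLASSES:
            raise ValueError(f"unknown HLC class {self.hlc_class!r}")
        if not self.required_activities:
            raise ValueError("required_activities must be non-empty")
        bad = set(self.required_activities) - set(ACTIVITIES)
        if bad:
            raise ValueError(f"unknown activity labels {sorted(bad)}")
        if not isinstance(self.allowed_locations, _Any):
            bad = set(self.allowed_locations) - set(LOCATIONS)
            if bad:
                raise ValueError(f"unknown location labels {sorted(bad)}")
        if not isinstance(self.allowed_emotions, _Any):
            bad = set(self.allowed_emotions) - set(EMOTIONS)
            if bad:
                raise ValueError(f"unknown emotion labels {sorted(bad)}")

    def matches(self, labels: dict[str, str]) -> bool:
        """True when a {category: label} composition satisfies this rule.

        A missing category matches ``ANY`` but never an explicit allowed
        set: a rule requiring a location cannot fire without one.
        """
        activity = labels.get("activity")
        if activity is None or activity not in self.required_activities:
            return False
        for category, allowed in (
            ("location", self.allowed_locations),
            ("emotion", self.allowed_emotions),
        ):
            if isinstance(allowed, _Any):
                continue
            label = labels.get(category)
            if label is None or label not in allowed:
                return False
        return True


def default_definitions() -> list[HlcDefinition]:
    """The packaged definitional model for the five HLC classes.

    Emotions are deliberately unconstrained (``ANY``) in every rule: the
    high-level state of a person is read off what they do and where, not
    how they sound, which is what makes the high-level timeline robust to
    emotion misrecognitions.
    """
    mk = HlcDefinition
    return [
        mk("OfficeWork", frozenset({"Sitting"}), frozenset({"Office"}), ANY, 1),
        mk("HavingMeal", frozenset({"Eating"}),
           frozenset({"Home", "Restaurant"}), ANY, 2),
        mk("Housework", frozenset({"Sweeping"}), frozenset({"Home"}), ANY, 3),
        mk("Exercising", frozenset({"Running", "Stretching", "Walking"}),
           frozenset({"Gym"}), ANY, 4),
        mk("Exercising", frozenset({"Running"}), ANY, ANY, 5),
        mk("Inactivity", frozenset({"Sitting", "Standing", "LyingDown"}),
           ANY, ANY, 6),
    ]


def default_definitions_path() -> Path:
    """Path of the packaged definitions config (mirrors default_definitions)."""
    return Path(__file__).parent / "data" / "defs.yaml"


def load_definitions(config_path: Union[str, Path]) -> list[HlcDefinition]:
    """Load HLC definitions from a YAML/JSON config file.

    Each entry carries ``{class, activities, locations, emotions, priority}``
    where ``locations``/``emotions`` may be the string ``"ANY"`` (or be
    omitted) to accept anything.
    """
    path = Path(config_path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of definitions")
    defs = []
    for entry in raw:
        defs.append(HlcDefinition(
            hlc_class=entry["class"],
            required_activities=frozenset(entry["activities"]),
            allowed_locations=_parse_allowed(entry.get("locations", "ANY")),
            allowed_emotions=_parse_allowed(entry.get("emotions", "ANY")),
            priority=int(entry["priority"]),
        ))
    priorities = [d.priority for d in defs]
    if len(set(priorities)) != len(priorities):
        raise ValueError("definition priorities must be unique")
    return defs


def _parse_allowed(value) -> AllowedSet:
    if value == "ANY" or value is None:
        return ANY
    return frozenset(value)


def dump_definitions(defs: Sequence[HlcDefinition], path: Union[str, Path]) -> None:
    """Write definitions back out as YAML (round-trips load_definitions)."""
    entries = []
    for d in defs:
        entries.append({
            "class": d.hlc_class,
            "activities": sorted(d.required_activities),
            "locations": "ANY" if isinstance(d.allowed_locations, _Any)
            else sorted(d.allowed_locations),
            "emotions": "ANY" if isinstance(d.allowed_emotions, _Any)
            else sorted(d.allowed_emotions),
            "priority": d.priority,
        })
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Verification and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Verdict:
    valid: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.valid


def validate_hlc(hlc: HighLevelContext) -> Verdict:
    """Consistency check on an unclassified HLC instance.

    Valid iff every constituent belongs to the same user, categories are
    not duplicated, all labels are legal for their category, and every
    constituent interval contains the instance start time.
    """
    seen: set[str] = set()
    for llc in hlc.constituents:
        if llc.user_id != hlc.user_id:
            return Verdict(False, f"constituent user {llc.user_id!r} differs")
        if llc.category in seen:
            return Verdict(False, f"duplicate category {llc.category!r}")
        seen.add(llc.category)
        if llc.label not in LABELS_BY_CATEGORY[llc.category]:
            return Verdict(False, f"illegal label {llc.label!r}")
        if not llc.contains(hlc.t_start):
            return Verdict(
                False,
                f"{llc.category} constituent not concurrent at t={hlc.t_start}",
            )
    return Verdict(True)


def classify_hlc(
    hlc: HighLevelContext, defs: Sequence[HlcDefinition]
) -> str:
    """Return the class of the best-priority matching definition.

    Pure function of (composition, definitions); ``Unclassified`` when no
    definition matches.
    """
    if not defs:
        raise ValueError("definitions list is empty")
    labels = hlc.labels
    for d in sorted(defs, key=lambda d: d.priority):
        if d.matches(labels):
            return d.hlc_class
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# Optional RDF export
# ---------------------------------------------------------------------------

def export_turtle(
    hlcs: Iterable[HighLevelContext],
    path: Union[str, Path],
    base_iri: str = "http://mcmine.example/context#",
) -> None:
    """Export classified HLC instances as RDF/Turtle triples."""
    from rdflib import Graph, Literal, Namespace, RDF, URIRef
    from rdflib.namespace import XSD

    ns = Namespace(base_iri)
    g = Graph()
    g.bind("ctx", ns)
    for i, hlc in enumerate(hlcs):
        subj = URIRef(f"{base_iri}hlc/{hlc.user_id}/{i}")
        g.add((subj, RDF.type, ns[hlc.hlc_class]))
        g.add((subj, ns.hasUser, Literal(hlc.user_id)))
        g.add((subj, ns.hasStartTime,
               Literal(hlc.t_start, datatype=XSD.double)))
        if hlc.t_end is not None:
            g.add((subj, ns.hasEndTime,
                   Literal(hlc.t_end, datatype=XSD.double)))
        preds = {"activity": ns.hasActivity, "emotion": ns.hasEmotion,
                 "location": ns.hasLocation}
        for llc in hlc.constituents:
            g.add((subj, preds[llc.category], ns[llc.label]))
    g.serialize(destination=str(path), format="turtle")
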