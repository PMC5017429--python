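"""Decision unification and change-only notification.

Each recognizer may emit several decisions within a fusion slot (3 s by
default).  Vertical fusion collapses one recognizer's decisions in a slot
to a single label by simple majority (ties go to the most recent
decision).  Horizontal fusion combines the per-recognizer labels of one
context category by weighted majority voting; weights are estimated from
each recognizer's recognition performance and renormalized over the
recognizers actually present in the slot.  The notifier then emits an
event only when the fused label differs from the last notified one, and a
finalization event when a stream goes quiet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .contexts import CATEGORIES, LABELS_BY_CATEGORY

DEFAULT_SLOT_S = 3.0

#: weights estimated from the recognition performance of the two activity
#: recognizers: inertial decisions are subtly favoured over video ones.
DEFAULT_ACTIVITY_WEIGHTS: dict[str, float] = {
    "inertial_activity": 0.5076,
    "video_activity": 0.4924,
}


class Final:
    """Marker passed to the notifier when a context stream goes quiet."""

    def __repr__(self) -> str:  # pragma: no cover
        return "FINAL"


FINAL = Final()


@dataclass(frozen=True)
class RecognizerDecision:
    recognizer_id: str
    user_id: str
    category: str
    label: str
    t: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.label not in LABELS_BY_CATEGORY[self.category]:
            raise ValueError(
                f"label {self.label!r} illegal for category {self.category!r}")


@dataclass
class FusionConfig:
    slot_s: float = DEFAULT_SLOT_S
    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_WEIGHTS))

    def __post_init__(self) -> None:
        if self.slot_s <= 0:
            raise ValueError("slot length must be positive")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")


def vertical_fuse(decisions: Sequence[RecognizerDecision]) -> Optional[str]:
    """Majority label of one recognizer's decisions in a slot.

    Empty input fuses to None; a vote tie goes to the label with the most
    recent decision (recency as a freshness proxy).
    """
    if not decisions:
        return None
    if len({d.recognizer_id for d in decisions}) > 1:
        raise ValueError("vertical fusion mixes recognizers")
    counts: dict[str, int] = {}
    latest: dict[str, float] = {}
    for d in decisions:
        counts[d.label] = counts.get(d.label, 0) + 1
        latest[d.label] = max(latest.get(d.label, float("-inf")), d.t)
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    return max(tied, key=lambda lab: latest[lab])


def horizontal_fuse(per_recognizer: Mapping[str, str],
                    cfg: FusionConfig) -> str:
    """Weighted majority vote across the recognizers of one category.

    Absent recognizers contribute nothing; the weights of the present ones
    are renormalized, so the result is invariant to uniform weight scaling.
    Unknown recognizers default to weight 1 (single-recognizer categories
    need no configured weight).
    """
    if not per_recognizer:
        raise ValueError("no recognizer votes")
    total = sum(cfg.weights.get(r, 1.0) for r in per_recognizer)
    scores: dict[str, float] = {}
    for rid, label in per_recognizer.items():
        scores[label] = scores.get(label, 0.0) + cfg.weights.get(rid, 1.0) / total
    best = max(scores.values())
    # exact ties (possible only with equal weights) break lexicographically
    return min(lab for lab, s in scores.items() if s >= best - 1e-12)


def estimate_weights(accuracies: Mapping[str, float]) -> dict[str, float]:
    """Performance-proportional weights: w_i = a_i / sum(a)."""
    if not accuracies:
        raise ValueError("no accuracies given")
    if any(a < 0 for a in accuracies.values()):
        raise ValueError("accuracies must be non-negative")
    total = sum(accuracies.values())
    if total == 0:
        raise ValueError("all accuracies are zero")
    return {rid: a / total for rid, a in accuracies.items()}


@dataclass(frozen=True)
class ContextEvent:
    """A change-only notification record (JSON-lines friendly)."""

    user_id: str
    category: str
    label: Optional[str]
    t: float
    kind: str  # "change" | "final"

    def to_dict(self) -> dict:
        return {"user": self.user_id, "category": self.category,
                "label": self.label, "t": self.t, "kind": self.kind}


class ChangeNotifier:
    """Per-(user, category) state machine emitting change/final events."""

    def __init__(self) -> None:
        self._last: dict[tuple[str, str], Optional[str]] = {}

    def last_label(self, user_id: str, category: str) -> Optional[str]:
        return self._last.get((user_id, category))

    def notify(self, user_id: str, category: str, label, t: float
               ) -> Optional[ContextEvent]:
        """Process a fused label (or FINAL); return an event or None.

        State is updated only when an event is emitted.
        """
        key = (user_id, category)
        last = self._last.get(key)
        if isinstance(label, Final):
            if last is None:
                return None  # nothing open to finalize
            self._last[key] = None
            return ContextEvent(user_id, category, last, t, "final")
        if label not in LABELS_BY_CATEGORY[category]:
            raise ValueError(
                f"label {label!r} illegal for category {category!r}")
        if label == last:
            return None
        self._last[key] = label
        return ContextEvent(user_id, category, label, t, "change")
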