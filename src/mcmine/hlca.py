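"""High-level context awareness: build, verify, classify, notify, persist.

Incoming low-level context events open and close interval records in an
append-only store.  Every change triggers an inference: the concurrent
low-level contexts of the user are gathered, composed into an unclassified
high-level context, verified and classified against the definitional
model, persisted, and notified — but only when the high-level class
actually changed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

from .contexts import (
    CATEGORIES,
    HighLevelContext,
    HlcDefinition,
    LowLevelContext,
    UNCLASSIFIED,
    classify_hlc,
    default_definitions,
    validate_hlc,
)
from .fusion import ContextEvent


class StoreCorruptionError(RuntimeError):
    """An invariant of the context store was violated."""


@dataclass(frozen=True)
class ConcurrencyQuery:
    user_id: str
    t: float
    exclude_category: Optional[str] = None


class ContextStore:
    """Append-only store of low- and high-level context records.

    Invariants: at most one OPEN low-level context per (user, category) and
    at most one OPEN high-level context per user.  Closed low-level
    records are kept per user sorted by start time so concurrency queries
    scan only a bounded suffix.
    """

    def __init__(self) -> None:
        self._closed_llc: dict[str, list[LowLevelContext]] = {}
        self._closed_starts: dict[str, list[float]] = {}
        self._open_llc: dict[tuple[str, str], LowLevelContext] = {}
        self.hlcs: list[HighLevelContext] = []
        self._open_hlc: dict[str, HighLevelContext] = {}

    # -- low-level records ------------------------------------------------

    def open_llc(self, user_id: str, category: str
                 ) -> Optional[LowLevelContext]:
        return self._open_llc.get((user_id, category))

    def all_llcs(self, user_id: str) -> list[LowLevelContext]:
        out = list(self._closed_llc.get(user_id, []))
        out.extend(v for (u, _), v in self._open_llc.items() if u == user_id)
        return out

    def store_llc(self, llc: LowLevelContext) -> None:
        key = (llc.user_id, llc.category)
        if llc.t_end is None:
            if key in self._open_llc:
                raise StoreCorruptionError(
                    f"open {llc.category} context already exists for "
                    f"{llc.user_id}")
            self._open_llc[key] = llc
        else:
            starts = self._closed_starts.setdefault(llc.user_id, [])
            rows = self._closed_llc.setdefault(llc.user_id, [])
            i = bisect.bisect_right(starts, llc.t_start)
            starts.insert(i, llc.t_start)
            rows.insert(i, llc)

    def close_llc(self, user_id: str, category: str, t_end: float
                  ) -> Optional[LowLevelContext]:
        """Close the open context of a category; return the closed record."""
        key = (user_id, category)
        open_ctx = self._open_llc.pop(key, None)
        if open_ctx is None:
            return None
        if t_end <= open_ctx.t_start:
            # zero-length context: drop rather than store an empty interval
            return open_ctx
        closed = LowLevelContext(open_ctx.user_id, open_ctx.category,
                                 open_ctx.label, open_ctx.t_start, t_end)
        self.store_llc(closed)
        return closed

    # -- high-level records -----------------------------------------------

    def store_hlc(self, hlc: HighLevelContext) -> None:
        prev = self._open_hlc.get(hlc.user_id)
        if prev is not None and prev.t_end is None:
            prev.t_end = hlc.t_start
        self.hlcs.append(hlc)
        if hlc.t_end is None:
            self._open_hlc[hlc.user_id] = hlc

    # -- queries ----------------------------------------------------------

    def query_concurrent(self, q: ConcurrencyQuery) -> list[LowLevelContext]:
        """All of the user's contexts valid at instant ``q.t``.

        Containment follows the half-open convention, so a context ending
        exactly at ``q.t`` is excluded.  Results come ordered by category.
        """
        hits: list[LowLevelContext] = []
        for category in CATEGORIES:
            if category == q.exclude_category:
                continue
            open_ctx = self._open_llc.get((q.user_id, category))
            if open_ctx is not None and open_ctx.contains(q.t):
                hits.append(open_ctx)
        rows = self._closed_llc.get(q.user_id, [])
        starts = self._closed_starts.get(q.user_id, [])
        # only records starting at or before t can contain it
        hi = bisect.bisect_right(starts, q.t)
        for llc in rows[:hi]:
            if llc.category == q.exclude_category:
                continue
            if llc.contains(q.t):
                hits.append(llc)
        hits.sort(key=lambda c: (CATEGORIES.index(c.category), c.t_start))
        return hits


# ---------------------------------------------------------------------------
# Builder / reasoner operations
# ---------------------------------------------------------------------------

def map_notification(store: ContextStore, event: ContextEvent
                     ) -> Optional[LowLevelContext]:
    """Apply a low-level event to the store.

    A change event closes the open context of its category at the event
    time and opens a new one; a final event only closes.  Returns the
    newly opened context, or None for finalizations.
    """
    if event.kind == "final":
        store.close_llc(event.user_id, event.category, event.t)
        return None
    store.close_llc(event.user_id, event.category, event.t)
    llc = LowLevelContext(event.user_id, event.category, event.label, event.t)
    store.store_llc(llc)
    return llc


def build_hlc(new_llc: LowLevelContext,
              concurrent: Sequence[LowLevelContext]) -> HighLevelContext:
    """Unclassified HLC from the triggering context plus its concurrents."""
    constituents = (new_llc, *concurrent)
    categories = [c.category for c in constituents]
    if len(set(categories)) != len(categories):
        raise StoreCorruptionError(
            f"duplicate category among constituents: {categories}")
    return HighLevelContext(
        user_id=new_llc.user_id,
        constituents=constituents,
        t_start=new_llc.t_start,
    )


def infer(hlc: HighLevelContext, defs: Sequence[HlcDefinition]
          ) -> HighLevelContext:
    """Verify then classify; invalid compositions stay Unclassified."""
    verdict = validate_hlc(hlc)
    hlc.hlc_class = classify_hlc(hlc, defs) if verdict else UNCLASSIFIED
    return hlc


@dataclass(frozen=True)
class HlcEvent:
    user_id: str
    hlc_class: str
    t: float

    def to_dict(self) -> dict:
        return {"user": self.user_id, "class": self.hlc_class, "t": self.t}


class HlcNotifier:
    """Emits an event only when the user's high-level class changes."""

    def __init__(self) -> None:
        self._last: dict[str, Optional[str]] = {}

    def last_class(self, user_id: str) -> Optional[str]:
        return self._last.get(user_id)

    def notify(self, classified: HighLevelContext) -> Optional[HlcEvent]:
        last = self._last.get(classified.user_id)
        if classified.hlc_class == last:
            return None
        self._last[classified.user_id] = classified.hlc_class
        return HlcEvent(classified.user_id, classified.hlc_class,
                        classified.t_start)


class HlcaEngine:
    """End-to-end high-level context awareness over a low-level event feed."""

    def __init__(self, defs: Optional[Sequence[HlcDefinition]] = None
                 ) -> None:
        self.defs = list(defs) if defs is not None else default_definitions()
        self.store = ContextStore()
        self.notifier = HlcNotifier()
        self.events: list[HlcEvent] = []

    def reload_definitions(self, defs: Sequence[HlcDefinition]) -> None:
        """Swap the definitional model at runtime (terminology update)."""
        self.defs = list(defs)

    def on_llc_event(self, event: ContextEvent) -> Optional[HlcEvent]:
        """Process one low-level notification; return an HLC event if any."""
        new_llc = map_notification(self.store, event)
        if new_llc is not None:
            concurrent = self.store.query_concurrent(ConcurrencyQuery(
                event.user_id, new_llc.t_start,
                exclude_category=event.category))
            hlc = build_hlc(new_llc, concurrent)
        else:
            # finalization: re-infer with the reduced composition
            remaining = self.store.query_concurrent(ConcurrencyQuery(
                event.user_id, event.t, exclude_category=event.category))
            remaining = [c for c in remaining if c.t_end is None]
            if not remaining:
                return None
            hlc = HighLevelContext(event.user_id, tuple(remaining), event.t)
        infer(hlc, self.defs)
        self.store.store_hlc(hlc)
        out = self.notifier.notify(hlc)
        if out is not None:
            self.events.append(out)
        return out
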