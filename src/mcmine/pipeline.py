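"""End-to-end streaming engine: router -> recognizers -> unifiers -> HLCA.

Packets are ingested in time order.  The router buffers each stream and
emits analysis windows; recognizers turn windows into labelled decisions;
decisions are pooled into 3-s fusion slots aligned to the session origin.
At each slot boundary the decisions of the elapsed slot are fused
(vertically per recognizer, then horizontally per category with the
configured weights), the change-only notifier turns fused labels into
low-level context events, and the high-level context awareness engine
updates the user's high-level timeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .audio import AudioEmotionRecognizer
from .contexts import HlcDefinition, SensoryPacket, UNKNOWN_PLACE
from .fusion import (
    ChangeNotifier,
    ContextEvent,
    FINAL,
    FusionConfig,
    RecognizerDecision,
    horizontal_fuse,
    vertical_fuse,
)
from .geo import GPS_DROPOUT_S, GeoLocationRecognizer, GpsFix
from .hlca import HlcaEngine, HlcEvent
from .inertial import InertialActivityRecognizer
from .router import RecognizerSpec, SensoryRouter, Window
from .skeleton import SkeletonActivityRecognizer

#: context categories that are finalized after this many seconds of silence
STREAM_TIMEOUT_S = {"location": GPS_DROPOUT_S, "emotion": 5.0}


@dataclass
class PipelineResult:
    llc_events: list[ContextEvent] = field(default_factory=list)
    hlc_events: list[HlcEvent] = field(default_factory=list)
    decisions: list[RecognizerDecision] = field(default_factory=list)

    def write_events(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.llc_events:
                fh.write(json.dumps(ev.to_dict()) + "\n")


class ContextPipeline:
    """Single-user, in-process realization of the full context stack."""

    def __init__(self,
                 inertial: InertialActivityRecognizer,
                 skeleton: Optional[SkeletonActivityRecognizer],
                 emotion: Optional[AudioEmotionRecognizer],
                 location: GeoLocationRecognizer,
                 defs: Optional[Sequence[HlcDefinition]] = None,
                 fusion_cfg: Optional[FusionConfig] = None) -> None:
        self.recognizers = {
            r.recognizer_id: r for r in
            (inertial, skeleton, emotion, location) if r is not None
        }
        self.cfg = fusion_cfg if fusion_cfg is not None else FusionConfig()
        self.router = SensoryRouter()
        self.router.register(RecognizerSpec(
            inertial.recognizer_id, frozenset({"inertial"}), 3.0, 3.0))
        if skeleton is not None:
            self.router.register(RecognizerSpec(
                skeleton.recognizer_id, frozenset({"skeleton"}), 3.0, 1.5))
        if emotion is not None:
            self.router.register(RecognizerSpec(
                emotion.recognizer_id, frozenset({"audio"}), 3.0, 3.0))
        self.router.register(RecognizerSpec(
            location.recognizer_id, frozenset({"gps"}), 1.0, 1.0))
        self.notifier = ChangeNotifier()
        self.hlca = HlcaEngine(defs)
        self.result = PipelineResult()
        self._slot_decisions: dict[tuple[str, str], list[RecognizerDecision]] = {}
        self._slot_index: Optional[int] = None
        self._last_decision_t: dict[str, float] = {}
        self._user: Optional[str] = None

    # -- streaming ---------------------------------------------------------

    def process(self, packets: Sequence[SensoryPacket]) -> PipelineResult:
        for packet in packets:
            self.push(packet)
        self.finish()
        return self.result

    def push(self, packet: SensoryPacket) -> None:
        self._user = packet.user_id
        slot = int(packet.t_start // self.cfg.slot_s)
        if self._slot_index is None:
            self._slot_index = slot
        # ingest first: a packet of slot k may complete straddling windows
        # that still belong to earlier slots
        for rid, windows in self.router.ingest(packet).items():
            for window in windows:
                self._decide(rid, window)
        # a packet starting in slot k proves slots < k complete
        while self._slot_index < slot:
            self._close_slot(self._slot_index)
            self._slot_index += 1

    def finish(self) -> None:
        """Flush the trailing slots after the last packet."""
        if self._slot_index is None:
            return
        self._close_slot(self._slot_index)
        self._slot_index += 1
        while self._slot_decisions:  # drain any retained future decisions
            self._close_slot(self._slot_index)
            self._slot_index += 1

    # -- internals ----------------------------------------------------------

    def _decide(self, rid: str, window: Window) -> None:
        recognizer = self.recognizers[rid]
        labels: list[tuple[float, str]] = []
        if rid == "geo_location":
            # one decision per fix
            for i, (lat, lon) in enumerate(window.samples):
                t = window.t_start + i / window.sampling_rate
                label = recognizer.predict_fix(GpsFix(t, lat, lon))
                if label != UNKNOWN_PLACE:
                    labels.append((t, label))
        elif rid == "audio_emotion":
            label = recognizer.predict_window(window.samples[:, 0],
                                              window.sampling_rate)
            if label is not None:
                labels.append((window.t_start, label))
        elif rid == "video_activity":
            n = window.samples.shape[0]
            frames = window.samples.reshape(n, -1, 3)
            labels.append((window.t_start, recognizer.predict_window(frames)))
        else:
            labels.append((window.t_start,
                           recognizer.predict_window(window.samples)))
        category = recognizer.category
        for t, label in labels:
            d = RecognizerDecision(rid, window.user_id, category, label, t)
            self.result.decisions.append(d)
            self._slot_decisions.setdefault((category, rid), []).append(d)
            self._last_decision_t[category] = max(
                self._last_decision_t.get(category, float("-inf")), t)

    def _close_slot(self, slot_index: int) -> None:
        if self._user is None:
            return
        t_slot = slot_index * self.cfg.slot_s
        t_next = t_slot + self.cfg.slot_s
        # vertical fusion per recognizer, grouped by category; decisions
        # timestamped beyond this slot are retained for the next one
        votes_by_category: dict[str, dict[str, str]] = {}
        for (category, rid), decisions in list(self._slot_decisions.items()):
            in_slot = [d for d in decisions if t_slot <= d.t < t_next]
            future = [d for d in decisions if d.t >= t_next]
            if future:
                self._slot_decisions[(category, rid)] = future
            else:
                del self._slot_decisions[(category, rid)]
            fused = vertical_fuse(in_slot)
            if fused is not None:
                votes_by_category.setdefault(category, {})[rid] = fused
        # horizontal fusion and notification per category
        for category, votes in votes_by_category.items():
            label = horizontal_fuse(votes, self.cfg)
            self._emit(category, label, t_slot)
        # finalize categories whose stream went quiet
        for category, timeout in STREAM_TIMEOUT_S.items():
            if category in votes_by_category:
                continue
            last = self._last_decision_t.get(category)
            if last is not None and t_next - last > timeout:
                self._emit(category, FINAL, t_slot)

    def _emit(self, category: str, label, t: float) -> None:
        event = self.notifier.notify(self._user, category, label, t)
        if event is None:
            return
        self.result.llc_events.append(event)
        hlc_event = self.hlca.on_llc_event(event)
        if hlc_event is not None:
            self.result.hlc_events.append(hlc_event)
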