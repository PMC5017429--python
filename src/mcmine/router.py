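"""Sensory data router: subscription registry and per-stream window buffers.

Recognizers subscribe with the modalities they accept, a minimum window
length and a hop.  Incoming packets are broadcast to every recognizer whose
accepted modalities include the packet's modality; per-(user, recognizer)
buffers cache samples until full windows of ``min_window`` seconds are
available, emitted every ``hop`` seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contexts import MODALITIES, SensoryPacket

log = logging.getLogger(__name__)


class OutOfOrderError(ValueError):
    """Raised when a packet's samples precede already-buffered data."""


@dataclass(frozen=True)
class RecognizerSpec:
    recognizer_id: str
    accepted_modalities: frozenset
    min_window: float
    hop: float

    def __post_init__(self) -> None:
        if self.min_window <= 0:
            raise ValueError("min_window must be positive")
        if not (0 < self.hop <= self.min_window):
            raise ValueError("hop must satisfy 0 < hop <= min_window")
        bad = set(self.accepted_modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities {sorted(bad)}")


@dataclass
class Window:
    """A complete analysis window cut from one (user, recognizer) stream."""

    user_id: str
    recognizer_id: str
    t_start: float
    sampling_rate: float
    samples: np.ndarray  # (n_window, n_channels)


class StreamBuffer:
    """Caches one stream and emits fixed-length windows on a hop grid.

    The window sample count is ``round(min_window * rate)`` and the hop
    advance ``round(hop * rate)`` samples; already-emitted data older than
    the next window start is evicted.
    """

    def __init__(self, spec: RecognizerSpec, user_id: str,
                 sampling_rate: float) -> None:
        self.spec = spec
        self.user_id = user_id
        self.rate = float(sampling_rate)
        self.n_window = int(round(spec.min_window * self.rate))
        self.n_hop = int(round(spec.hop * self.rate))
        if self.n_window < 1 or self.n_hop < 1:
            raise ValueError("window/hop shorter than one sample period")
        self._chunks: list[np.ndarray] = []
        self._buf_t0: Optional[float] = None  # time of first buffered sample
        self._next_t: Optional[float] = None  # expected next sample time

    def push_and_emit(self, packet: SensoryPacket) -> list[Window]:
        """Append a packet; return every newly completed window."""
        if self._next_t is not None and packet.t_start < self._next_t - 0.5 / self.rate:
            raise OutOfOrderError(
                f"packet at t={packet.t_start} precedes buffered data "
                f"ending at t={self._next_t}"
            )
        if self._next_t is not None and packet.t_start > self._next_t + 0.5 / self.rate:
            # gap in the stream: drop the stale partial window and restart
            log.debug("stream gap of %.3f s for %s/%s; buffer reset",
                      packet.t_start - self._next_t, self.user_id,
                      self.spec.recognizer_id)
            self._chunks = []
            self._buf_t0 = None
        if self._buf_t0 is None:
            self._buf_t0 = packet.t_start
        self._next_t = packet.t_end
        self._chunks.append(packet.samples)

        data = np.concatenate(self._chunks, axis=0) if len(self._chunks) > 1 \
            else self._chunks[0]
        windows: list[Window] = []
        start = 0
        while start + self.n_window <= data.shape[0]:
            windows.append(Window(
                user_id=self.user_id,
                recognizer_id=self.spec.recognizer_id,
                t_start=self._buf_t0 + start / self.rate,
                sampling_rate=self.rate,
                samples=data[start:start + self.n_window].copy(),
            ))
            start += self.n_hop
        # evict everything before the next window start
        if start > 0:
            data = data[start:]
            self._buf_t0 += start / self.rate
        self._chunks = [data]
        return windows


class SensoryRouter:
    """Cross-matches packets against the registry and feeds buffers."""

    def __init__(self) -> None:
        self._registry: dict[str, RecognizerSpec] = {}
        self._buffers: dict[tuple[str, str], StreamBuffer] = {}

    def register(self, spec: RecognizerSpec) -> RecognizerSpec:
        if spec.recognizer_id in self._registry:
            raise ValueError(f"recognizer {spec.recognizer_id!r} already registered")
        self._registry[spec.recognizer_id] = spec
        return spec

    @property
    def registry(self) -> dict[str, RecognizerSpec]:
        return dict(self._registry)

    def route_packet(self, packet: SensoryPacket) -> list[str]:
        """Recognizer ids whose accepted modalities match the packet."""
        matched = sorted(
            rid for rid, spec in self._registry.items()
            if packet.modality in spec.accepted_modalities
        )
        if not matched:
            log.debug("dropping %s packet for %s: no subscriber",
                      packet.modality, packet.user_id)
        return matched

    def ingest(self, packet: SensoryPacket) -> dict[str, list[Window]]:
        """Route a packet, buffer it, and return ready windows per recognizer."""
        out: dict[str, list[Window]] = {}
        for rid in self.route_packet(packet):
            key = (packet.user_id, rid)
            buf = self._buffers.get(key)
            if buf is None:
                buf = StreamBuffer(self._registry[rid], packet.user_id,
                                   packet.sampling_rate)
                self._buffers[key] = buf
            windows = buf.push_and_emit(packet)
            if windows:
                out[rid] = windows
        return out
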