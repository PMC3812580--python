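"""Mapping detection events to sound triggers.

The movement-to-sound mapping is the experimental variable of the whole
system: which sound a thrust or shake elicits, and how loud, can be
changed between (or during) sessions.  A mapping is a list of rules —
(event kind, magnitude range) -> (sound id, gain) — with a named gain
curve: ``constant`` plays at the rule's gain, ``linear`` scales the
gain with the event magnitude across the rule's range (so stronger
shakes play louder), and ``breakpoints`` interpolates a user-supplied
monotone magnitude->gain table.

Playback is dispatched through an abstract sink; a null sink and a CSV
file sink ship for silent operation and testing, and any object with a
``play(trigger, t_ms)`` method (e.g. a thin wrapper over an audio
library) can be plugged in.
"""

from __future__ import annotations

import csv
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .strain import DetectionEvent

logger = logging.getLogger(__name__)


class NoRuleError(KeyError):
    """No mapping rule covers an event's kind and magnitude."""


@dataclass(frozen=True)
class MappingRule:
    kind: str                      # "thrust" | "shake"
    sound_id: str
    gain: float = 1.0              # gain at the top of the range (or constant)
    lo: float = 0.0                # magnitude range [lo, hi)
    hi: float = math.inf

    def __post_init__(self) -> None:
        if not (0.0 <= self.gain <= 1.0):
            raise ValueError("rule gain must lie in [0, 1]")
        if not self.lo < self.hi:
            raise ValueError("rule magnitude range must be non-empty")


@dataclass(frozen=True)
class SoundTrigger:
    sound_id: str
    gain: float


@dataclass(frozen=True)
class PlaybackRecord:
    t_ms: int
    sound_id: str
    gain: float
    source_event_magnitude: float


@dataclass(frozen=True)
class SoundMapping:
    """A validated set of rules plus a gain curve.

    ``gain_curve`` is ``"constant"``, ``"linear"`` (requires every rule
    to have a finite range), or a tuple of (magnitude, gain) breakpoints
    with nondecreasing gains.
    """

    rules: tuple[MappingRule, ...]
    gain_curve: str | tuple[tuple[float, float], ...] = "constant"

    def __post_init__(self) -> None:
        by_kind: dict[str, list[MappingRule]] = {}
        for r in self.rules:
            by_kind.setdefault(r.kind, []).append(r)
        for kind, rs in by_kind.items():
            rs = sorted(rs, key=lambda r: r.lo)
            for a, b in zip(rs, rs[1:]):
                if b.lo < a.hi:
                    raise ValueError(f"overlapping magnitude ranges for kind {kind!r}")
        if isinstance(self.gain_curve, str):
            if self.gain_curve not in ("constant", "linear"):
                raise ValueError("gain_curve must be 'constant', 'linear' or breakpoints")
            if self.gain_curve == "linear":
                for r in self.rules:
                    if not math.isfinite(r.hi):
                        raise ValueError("linear gain curve needs finite rule ranges")
        else:
            pts = tuple(self.gain_curve)
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            if sorted(xs) != xs or sorted(ys) != ys:
                raise ValueError("breakpoint gain curve must be monotone nondecreasing")
            if any(not 0 <= y <= 1 for y in ys):
                raise ValueError("breakpoint gains must lie in [0, 1]")


def _gain(mapping: SoundMapping, rule: MappingRule, magnitude: float) -> float:
    curve = mapping.gain_curve
    if curve == "constant":
        g = rule.gain
    elif curve == "linear":
        g = rule.gain * (magnitude - rule.lo) / (rule.hi - rule.lo)
    else:
        pts = tuple(curve)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        if magnitude <= xs[0]:
            g = ys[0]
        elif magnitude >= xs[-1]:
            g = ys[-1]
        else:
            for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
                if x0 <= magnitude <= x1:
                    g = y0 + (y1 - y0) * (magnitude - x0) / (x1 - x0) if x1 > x0 else y1
                    break
    return min(1.0, max(0.0, g))


def map_event(event: DetectionEvent, mapping: SoundMapping) -> SoundTrigger:
    """Deterministic rule lookup; gain from the curve, clipped to [0, 1]."""
    for rule in mapping.rules:
        if rule.kind == event.kind and rule.lo <= event.magnitude < rule.hi:
            return SoundTrigger(sound_id=rule.sound_id, gain=_gain(mapping, rule, event.magnitude))
    raise NoRuleError(f"no rule covers {event.kind} at magnitude {event.magnitude}")


class NullSink:
    """Discards triggers; useful for dry runs and tests."""

    def __init__(self) -> None:
        self.closed = False
        self.played: list[tuple[SoundTrigger, int]] = []

    def play(self, trigger: SoundTrigger, t_ms: int) -> None:
        self.played.append((trigger, t_ms))

    def close(self) -> None:
        self.closed = True


class FileSink:
    """Appends each trigger as a CSV row: t_ms, sound_id, gain."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self._fh = open(self.path, "w", newline="")
        self._writer = csv.writer(self._fh)
        self._writer.writerow(["t_ms", "sound_id", "gain"])
        self.closed = False

    def play(self, trigger: SoundTrigger, t_ms: int) -> None:
        self._writer.writerow([t_ms, trigger.sound_id, f"{trigger.gain:.6g}"])

    def close(self) -> None:
        self._fh.close()
        self.closed = True


def open_sink(spec: str):
    """Build a sink from a spec string: ``null`` or ``file:<path>``."""
    if spec == "null":
        return NullSink()
    if spec.startswith("file:"):
        return FileSink(spec[5:])
    raise ValueError(f"unknown sink spec {spec!r}")


def play(event: DetectionEvent, trigger: SoundTrigger, sink) -> PlaybackRecord:
    """Dispatch a trigger to a sink and return the timestamped record.

    The record keeps the event's logical timestamp; wall-clock dispatch
    latency is measured and logged at debug level so real-time behaviour
    can be audited without polluting the data path.
    """
    if getattr(sink, "closed", False):
        raise ValueError("playback sink is closed")
    start = time.perf_counter()
    sink.play(trigger, event.t_ms)
    latency_ms = (time.perf_counter() - start) * 1000.0
    logger.debug("dispatched %s at t=%d ms (latency %.3f ms)",
                 trigger.sound_id, event.t_ms, latency_ms)
    return PlaybackRecord(
        t_ms=event.t_ms,
        sound_id=trigger.sound_id,
        gain=trigger.gain,
        source_event_magnitude=event.magnitude,
    )


def load_mapping(source: str | Path | dict) -> SoundMapping:
    """Load a mapping from YAML (path or pre-parsed dict).

    Schema::

        gain_curve: constant            # or linear, or [[mag, gain], ...]
        rules:
          - {kind: thrust, sound: snare, gain: 1.0, lo: 0, hi: .inf}
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    rules = tuple(
        MappingRule(
            kind=r["kind"],
            sound_id=r.get("sound", r.get("sound_id")),
            gain=float(r.get("gain", 1.0)),
            lo=float(r.get("lo", 0.0)),
            hi=float(r.get("hi", math.inf)),
        )
        for r in data["rules"]
    )
    curve = data.get("gain_curve", "constant")
    if isinstance(curve, (list, tuple)):
        curve = tuple((float(x), float(y)) for x, y in curve)
    return SoundMapping(rules=rules, gain_curve=curve)


DEFAULT_MAPPING = SoundMapping(
    rules=(
        MappingRule(kind="thrust", sound_id="snare", gain=1.0),
        MappingRule(kind="shake", sound_id="rattle", gain=1.0),
    ),
    gain_curve="constant",
)
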