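"""Wireless acceleration pipeline.

A 3-axis accelerometer (±3 g span, 8 bits per axis, one sample every
10 ms) rides inside a resilient toy.  Sound is driven not by absolute
acceleration but by jerk — the Euclidean norm of per-axis differences
between consecutive samples — so the constant offsets of gravity, of
sensor bias, and of steady walking cancel out and only abrupt movements
(shakes, throws) remain.  An activation fires whenever jerk exceeds a
threshold; a continuously-reset timer then debounces dense activation
bursts so a sustained shake produces exactly one sound, at its first
activation, until a quiet period longer than the refractory interval
has elapsed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .strain import DetectionEvent, StreamError

AXIS_MAX = 255  # 8-bit raw counts per axis


@dataclass(frozen=True)
class MotionFrame:
    """One 3-axis acceleration sample at the nominal 10 ms cadence."""

    t_ms: int
    ax: int
    ay: int
    az: int

    def __post_init__(self) -> None:
        for v in (self.ax, self.ay, self.az):
            if not (0 <= v <= AXIS_MAX):
                raise ValueError(f"axis value {v} outside [0, {AXIS_MAX}]")


@dataclass(frozen=True)
class MotionConfig:
    """Tunables of the shake detector.

    ``activation_threshold`` is in raw counts of jerk; it is meant to be
    adjusted per wearer so that walking stays below it and shaking
    exceeds it.  ``refractory_ms`` is the quiet period the
    continuously-reset timer requires between sonified activations.
    """

    activation_threshold: float = 30.0
    refractory_ms: int = 300
    cadence_ms: int = 10
    jitter_ms: int = 2

    def __post_init__(self) -> None:
        if not self.activation_threshold > 0:
            raise ValueError("activation_threshold must be positive")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be non-negative")


def axis_deltas(prev: MotionFrame, cur: MotionFrame) -> tuple[int, int, int]:
    """Per-axis running difference between consecutive samples."""
    if cur.t_ms <= prev.t_ms:
        raise StreamError("motion frame timestamps must increase")
    return (cur.ax - prev.ax, cur.ay - prev.ay, cur.az - prev.az)


def jerk_norm(deltas: tuple[float, float, float]) -> float:
    """Euclidean norm of the per-axis deltas: the jerk magnitude."""
    dx, dy, dz = deltas
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def _validate_cadence(t: np.ndarray, cfg: MotionConfig) -> None:
    if t.size >= 2:
        gaps = np.diff(t)
        if np.any(gaps <= 0):
            raise StreamError("motion frame timestamps must be strictly increasing")
        lo = cfg.cadence_ms - cfg.jitter_ms
        hi = cfg.cadence_ms + cfg.jitter_ms
        if np.any(gaps < lo) or np.any(gaps > hi):
            raise StreamError(
                f"inter-sample gaps must stay within {lo}-{hi} ms "
                f"(nominal cadence {cfg.cadence_ms} ms)"
            )


def detect_shakes(
    stream: Iterable[MotionFrame], cfg: MotionConfig = MotionConfig()
) -> list[DetectionEvent]:
    """Jerk-threshold shake detection with a continuously-reset timer.

    An *activation* occurs at every sample whose jerk (relative to the
    previous sample) exceeds ``activation_threshold``.  An activation is
    sonified — emitted as an event — only if at least ``refractory_ms``
    have elapsed since the previous activation, emitted or not; every
    activation resets the timer.  Consequently a dense activation burst
    yields exactly one event, its first, and no further sound until the
    device has been quiet for a full refractory interval.

    The first frame of a stream has jerk defined as 0, so a single-frame
    stream yields nothing.
    """
    frames = list(stream)
    if len(frames) < 2:
        return []
    t = np.array([f.t_ms for f in frames], dtype=np.int64)
    _validate_cadence(t, cfg)
    a = np.array([[f.ax, f.ay, f.az] for f in frames], dtype=float)
    jerk = np.linalg.norm(np.diff(a, axis=0), axis=1)  # jerk[i-1] belongs to frame i

    events: list[DetectionEvent] = []
    last_activation: float = -math.inf
    for i in np.nonzero(jerk > cfg.activation_threshold)[0]:
        ti = int(t[i + 1])
        if ti - last_activation >= cfg.refractory_ms:
            events.append(DetectionEvent(t_ms=ti, kind="shake", magnitude=float(jerk[i])))
        last_activation = ti
    return events
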