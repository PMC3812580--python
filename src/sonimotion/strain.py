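"""Wired strain-sensing pipeline.

Four piezoelectric elements glued to a Plexiglas panel report strain as
10-bit integers (0-1023 per channel).  A microcontroller sums the four
concurrent readings (0-4092), gates out gentle touches, and discriminates
surface-displacing pushes ("thrusts") from superficial strikes ("hits")
with a two-stage threshold: a candidate opens when the sum exceeds the
stage-1 threshold, and an event fires only if the sum re-read 5 ms later
also exceeds the stage-2 threshold.  A refractory period then suppresses
further triggers so one movement elicits one sound.

This module implements that pipeline on timestamped frame streams, plus
the ASCII serial-line contract used to ship summed readings to the host
and the centroidal-Voronoi sensor placement on the panel.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

ADC_MAX = 1023          # 10-bit ADC, per channel
SUM_MAX = 4 * ADC_MAX   # 4092, the largest possible four-channel sum


class InvalidFrameError(ValueError):
    """A strain frame violates the per-channel 0-1023 range."""


class StreamError(ValueError):
    """A frame stream violates its ordering/cadence contract."""


@dataclass(frozen=True)
class StrainFrame:
    """One four-sensor strain sample.

    Parameters
    ----------
    t_ms : int
        Milliseconds since stream start; strictly increasing in a stream.
    channels : tuple of 4 ints
        Raw ADC counts, each in [0, 1023].
    """

    t_ms: int
    channels: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.channels) != 4:
            raise InvalidFrameError(f"expected 4 channels, got {len(self.channels)}")
        for c in self.channels:
            if not (0 <= c <= ADC_MAX):
                raise InvalidFrameError(f"channel value {c} outside [0, {ADC_MAX}]")


@dataclass(frozen=True)
class StrainConfig:
    """Tunables of the wired detector.

    Defaults are the calibrated operating point of the panel: gentle
    touches stay below ~500 summed counts (noise gate), any candidate
    manipulation exceeds 1000, and only thrusts still exceed 1765 when
    re-read 5 ms after the candidate opened.  A 300 ms refractory period
    debounces the serial link and guarantees one sound per movement.
    """

    noise_gate: int = 500
    stage1_threshold: int = 1000
    stage2_threshold: int = 1765
    stage2_delay_ms: int = 5
    refractory_ms: int = 300
    min_sample_interval_ms: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.noise_gate <= self.stage1_threshold <= self.stage2_threshold <= SUM_MAX):
            raise ValueError(
                "thresholds must satisfy 0 <= noise_gate <= stage1 <= stage2 <= "
                f"{SUM_MAX}"
            )
        if self.stage2_delay_ms <= 0:
            raise ValueError("stage2_delay_ms must be positive")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be non-negative")


@dataclass(frozen=True)
class DetectionEvent:
    """A detected thrust or shake, the bridge from sensing to sound.

    ``magnitude`` is the second-stage summed reading for thrusts and the
    jerk value for shakes; always positive.
    """

    t_ms: int
    kind: str  # "thrust" | "shake"
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("thrust", "shake"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.magnitude > 0:
            raise ValueError("event magnitude must be positive")


def sum_frame(frame: StrainFrame) -> int:
    """Sum the four concurrent channel readings; result in [0, 4092]."""
    s = 0
    for c in frame.channels:
        if not (0 <= c <= ADC_MAX):
            raise InvalidFrameError(f"channel value {c} outside [0, {ADC_MAX}]")
        s += c
    return s


def apply_noise_gate(summed: float, cfg: StrainConfig = StrainConfig()) -> bool:
    """True iff a summed reading passes the noise gate (strictly above it).

    The gate discards the low-strain touches a recording session should
    ignore; comparisons at every threshold in this pipeline are strict.
    """
    return summed > cfg.noise_gate


def _validate_stream_times(t_ms: np.ndarray, min_interval: int) -> None:
    if t_ms.size >= 2:
        gaps = np.diff(t_ms)
        if np.any(gaps <= 0):
            raise StreamError("frame timestamps must be strictly increasing")
        if np.any(gaps < min_interval):
            raise StreamError(
                f"frames closer than min_sample_interval_ms={min_interval}"
            )


def detect_thrusts_sums(
    t_ms: Sequence[int] | np.ndarray,
    sums: Sequence[float] | np.ndarray,
    cfg: StrainConfig = StrainConfig(),
) -> list[DetectionEvent]:
    """Two-stage thrust detection on a pre-summed reading stream.

    A frame at time ``t`` whose sum exceeds ``stage1_threshold`` opens a
    candidate; the nearest frame at or after ``t + stage2_delay_ms``
    (within twice the delay, so a dropped sample abandons the candidate)
    must exceed ``stage2_threshold`` for an event to fire at
    ``t + stage2_delay_ms`` with the second-stage sum as magnitude.
    After an emitted event, frames within ``refractory_ms`` of the
    stage-1 trigger are ignored entirely.
    """
    t = np.asarray(t_ms, dtype=np.int64)
    s = np.asarray(sums, dtype=float)
    if t.size == 0:
        return []
    if t.shape != s.shape:
        raise ValueError("t_ms and sums must have the same length")
    _validate_stream_times(t, cfg.min_sample_interval_ms)
    if np.any(s < 0) or np.any(s > SUM_MAX):
        raise StreamError(f"summed readings must lie in [0, {SUM_MAX}]")

    events: list[DetectionEvent] = []
    t_list = t.tolist()
    last_trigger = -math.inf
    for i in np.nonzero(s > cfg.stage1_threshold)[0]:
        ti = t_list[i]
        if ti - last_trigger < cfg.refractory_ms:
            continue
        j = bisect_left(t_list, ti + cfg.stage2_delay_ms)
        if j >= len(t_list) or t_list[j] - ti > 2 * cfg.stage2_delay_ms:
            continue  # sample dropped: abandon the candidate
        if s[j] > cfg.stage2_threshold:
            events.append(
                DetectionEvent(
                    t_ms=ti + cfg.stage2_delay_ms, kind="thrust", magnitude=float(s[j])
                )
            )
            last_trigger = ti
    return events


def detect_thrusts(
    stream: Iterable[StrainFrame], cfg: StrainConfig = StrainConfig()
) -> list[DetectionEvent]:
    """Run the two-stage thrust detector on a stream of strain frames."""
    frames = list(stream)
    if not frames:
        return []
    t = np.array([f.t_ms for f in frames], dtype=np.int64)
    s = np.array([sum_frame(f) for f in frames], dtype=float)
    return detect_thrusts_sums(t, s, cfg)


def parse_serial_line(line: str) -> int | None:
    """Parse one serial line into a summed reading, or reject it.

    The transport is ASCII decimal digits terminated by a newline.  A
    line is accepted iff, after stripping surrounding whitespace, it
    consists solely of ASCII digits; anything else (transmission noise,
    partial frames) is rejected silently — malformed lines are data, not
    faults.
    """
    s = line.strip()
    if s and s.isascii() and s.isdigit():
        return int(s)
    logger.debug("discarding malformed serial line %r", line)
    return None


def lloyd_step(
    points: np.ndarray, width: float, height: float, grid: int = 192
) -> np.ndarray:
    """One Lloyd iteration on the rectangle [0,width] x [0,height].

    Each generator moves to the centroid of its Voronoi cell, evaluated
    on a ``grid`` x ``grid`` quadrature of the rectangle.
    """
    pts = np.asarray(points, dtype=float)
    gx = (np.arange(grid) + 0.5) * (width / grid)
    gy = (np.arange(grid) + 0.5) * (height / grid)
    xx, yy = np.meshgrid(gx, gy)
    cells = np.column_stack([xx.ravel(), yy.ravel()])
    _, owner = cKDTree(pts).query(cells)
    out = pts.copy()
    for k in range(len(pts)):
        mine = cells[owner == k]
        if len(mine):
            out[k] = mine.mean(axis=0)
    return out


def sensor_layout(width: float, height: float, n: int = 4, seed: int = 0) -> np.ndarray:
    """Sensor positions inducing a centroidal Voronoi tessellation.

    Each sensor sits at the center of mass of its own Voronoi tile, the
    fixed point of Lloyd's algorithm, which minimizes the distance from
    any point of a tile to its sensor.  For the standard four-sensor
    panel this is the four quadrant centroids (±width/4, ±height/4 about
    the panel center); other ``n`` are solved by Lloyd iteration.

    Coordinates are corner-origin, x rightward, y upward, same length
    units as the inputs.  Rows are sorted by (y, x).
    """
    if width <= 0 or height <= 0:
        raise ValueError("panel dimensions must be positive")
    if n < 1:
        raise ValueError("need at least one sensor")
    if n == 4:
        pts = np.array(
            [
                [width / 4, height / 4],
                [3 * width / 4, height / 4],
                [width / 4, 3 * height / 4],
                [3 * width / 4, 3 * height / 4],
            ]
        )
        return pts
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0], [width, height], size=(n, 2))
    for _ in range(200):
        new = lloyd_step(pts, width, height)
        if np.max(np.abs(new - pts)) < 1e-9 * max(width, height):
            pts = new
            break
        pts = new
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]
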