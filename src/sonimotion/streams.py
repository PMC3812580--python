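"""CSV stream formats shared by the CLI and the library.

Wired streams: ``t_ms,s1,s2,s3,s4`` (one four-channel frame per row) or
the pre-summed variant ``t_ms,sum``.  Wireless streams:
``t_ms,ax,ay,az``.  Event files: ``t_ms,kind,magnitude``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .motion import MotionFrame
from .strain import DetectionEvent, StrainFrame


def read_strain_csv(path: str | Path) -> list[StrainFrame] | pd.DataFrame:
    """Read a wired stream; returns frames, or a DataFrame if pre-summed."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"t_ms", "s1", "s2", "s3", "s4"} <= cols:
        return [
            StrainFrame(t_ms=int(r.t_ms), channels=(int(r.s1), int(r.s2), int(r.s3), int(r.s4)))
            for r in df.itertuples()
        ]
    if {"t_ms", "sum"} <= cols:
        return df[[c for c in df.columns if c in ("t_ms", "sum", "height_cm")]]
    raise ValueError("strain CSV needs columns t_ms,s1..s4 or t_ms,sum")


def write_strain_csv(frames: Sequence[StrainFrame], path: str | Path) -> None:
    pd.DataFrame(
        [(f.t_ms, *f.channels) for f in frames],
        columns=["t_ms", "s1", "s2", "s3", "s4"],
    ).to_csv(path, index=False)


def read_motion_csv(path: str | Path) -> list[MotionFrame]:
    df = pd.read_csv(path)
    if not {"t_ms", "ax", "ay", "az"} <= set(df.columns):
        raise ValueError("motion CSV needs columns t_ms,ax,ay,az")
    return [
        MotionFrame(t_ms=int(r.t_ms), ax=int(r.ax), ay=int(r.ay), az=int(r.az))
        for r in df.itertuples()
    ]


def write_motion_csv(frames: Sequence[MotionFrame], path: str | Path) -> None:
    pd.DataFrame(
        [(f.t_ms, f.ax, f.ay, f.az) for f in frames],
        columns=["t_ms", "ax", "ay", "az"],
    ).to_csv(path, index=False)


def write_events_csv(events: Sequence[DetectionEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.t_ms, e.kind, e.magnitude) for e in events],
        columns=["t_ms", "kind", "magnitude"],
    ).to_csv(path, index=False)
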