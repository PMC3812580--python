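"""Timestamped CSV session logs with parameter headers.

Every experimental session writes a CSV log whose header block records
the active thresholds and sound mapping; whenever parameters change and
recording resumes, a fresh header block is appended before subsequent
rows, so the log is a self-describing record of what the device was
doing when.  Header lines are '#'-prefixed comments, keeping the file a
single parseable CSV.

Two buffering modes mirror the two pipelines: ``immediate`` flushes
every row as it is written (each reading is timestamped and persisted
at once, surviving a crash); ``buffered`` collects rows in memory and
writes them at session close.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .sonify import PlaybackRecord

COLUMNS = ["t_ms", "iso_time", "kind", "magnitude", "sound_id", "gain"]


@dataclass
class SessionBlock:
    """One parameter header block and the rows logged under it."""

    params: dict[str, str]
    rows: pd.DataFrame


class SessionLog:
    """Append-only session log; use as a context manager."""

    def __init__(self, path: str | Path, params: dict, mode: str = "immediate") -> None:
        if mode not in ("immediate", "buffered"):
            raise ValueError("mode must be 'immediate' or 'buffered'")
        self.path = Path(path)
        self.mode = mode
        self.closed = False
        self._buffer: list[str] = []
        self._last_t: int | None = None
        try:
            self._fh = open(self.path, "w", newline="")
        except OSError as exc:
            raise OSError(f"cannot open session log at {self.path}: {exc}") from exc
        self._write_header(params, first=True)

    def _write_header(self, params: dict, first: bool = False) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="milliseconds")
        lines = [f"# session_start={stamp}", f"# mode={self.mode}"]
        lines += [f"# {k}={v}" for k, v in params.items()]
        self._fh.write("\n".join(lines) + "\n")
        if first:
            self._fh.write(",".join(COLUMNS) + "\n")
        self._fh.flush()

    def update_params(self, params: dict) -> None:
        """Record a mid-session parameter change as a new header block."""
        self._require_open()
        self._flush_buffer()
        self._write_header(params)

    def log_event(self, record: PlaybackRecord, kind: str = "thrust") -> None:
        """Append one playback record as a data row."""
        self._require_open()
        if self._last_t is not None and record.t_ms < self._last_t:
            raise ValueError("log row timestamps must be nondecreasing")
        self._last_t = record.t_ms
        iso = _dt.datetime.now().isoformat(timespec="milliseconds")
        row = (
            f"{record.t_ms},{iso},{kind},{record.source_event_magnitude:.6g},"
            f"{record.sound_id},{record.gain:.6g}\n"
        )
        if self.mode == "immediate":
            self._fh.write(row)
            self._fh.flush()
        else:
            self._buffer.append(row)

    def _flush_buffer(self) -> None:
        if self._buffer:
            self._fh.writelines(self._buffer)
            self._buffer.clear()
            self._fh.flush()

    def _require_open(self) -> None:
        if self.closed:
            raise ValueError("session log is closed")

    def close(self) -> None:
        if not self.closed:
            self._flush_buffer()
            self._fh.close()
            self.closed = True

    def __enter__(self) -> "SessionLog":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_session(path: str | Path, params: dict, mode: str = "immediate") -> SessionLog:
    """Open a new session log and write its first parameter header."""
    return SessionLog(path, params, mode=mode)


def read_session_log(path: str | Path) -> list[SessionBlock]:
    """Parse a session log back into its header blocks and rows."""
    blocks: list[SessionBlock] = []
    params: dict[str, str] = {}
    rows: list[str] = []
    in_header = False

    def _close_block() -> None:
        nonlocal params, rows
        if params or rows:
            if rows:
                df = pd.read_csv(io.StringIO("".join(rows)), names=COLUMNS)
            else:
                df = pd.DataFrame(columns=COLUMNS)
            blocks.append(SessionBlock(params=params, rows=df))
        params, rows = {}, []

    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if not in_header:
                    _close_block()
                    in_header = True
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    params[k.strip()] = v.strip()
            else:
                in_header = False
                if line.strip() and line.strip() != ",".join(COLUMNS):
                    rows.append(line)
    _close_block()
    return blocks
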