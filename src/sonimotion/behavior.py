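"""Coded-behavior annotation parsing and summarization.

Interactions with the device are video-recorded and coded, individual
by individual, into time-aligned behavior annotations (approach,
recession, exploration, tool use, poking, pushing, hitting, dominance
display, and proximity within 2 m).  This module parses the
tab-delimited export of such annotations and reproduces the pilot
study's summary table: per-individual behavior counts, per-individual
proximity durations, a totals row, and the share of session time spent
under each sound-mapping condition.

Point behaviors (poke, push, hit) are zero-length intervals; only
proximity carries a meaningful duration.  Because several individuals
can be near the device at once, the group's summed proximity can
legitimately exceed the session length.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

BEHAVIORS = (
    "approach", "recession", "explore", "tool_use",
    "poke", "push", "hit", "display", "proximity",
)
CONDITIONS = ("snare", "hihat", "syllable", "none")

#: Sound-condition schedule of the pilot session (condition, start_ms,
#: end_ms): snare 69.5 %, hi-hat 1.5 %, spoken syllables 17.5 % and no
#: sound / no interaction 11.5 % of the ~33 min session.
PILOT_CONDITION_INTERVALS: tuple[tuple[str, int, int], ...] = (
    ("snare", 0, 1_376_100),
    ("hihat", 1_376_100, 1_405_800),
    ("syllable", 1_405_800, 1_752_300),
    ("none", 1_752_300, 1_980_000),
)
PILOT_SESSION_MS = 1_980_000

#: Per-individual pilot results: (proximity s, poke, tool_use, push, hit,
#: display) for the twelve chimpanzees that interacted with the device.
PILOT_TABLE: dict[str, tuple[int, int, int, int, int, int]] = {
    "C1": (211, 12, 2, 0, 0, 0),
    "C2": (140, 3, 0, 0, 0, 0),
    "C3": (122, 19, 0, 4, 3, 0),
    "C4": (211, 32, 3, 75, 0, 0),
    "C5": (32, 1, 0, 0, 0, 0),
    "C6": (68, 2, 0, 0, 0, 2),
    "C7": (517, 1, 0, 0, 0, 0),
    "C8": (288, 31, 5, 35, 51, 2),
    "C9": (458, 20, 10, 10, 0, 0),
    "C10": (6, 1, 0, 0, 0, 0),
    "C11": (243, 25, 1, 90, 0, 0),
    "C12": (20, 2, 0, 3, 0, 0),
}


class AnnotationParseError(ValueError):
    """A malformed annotation line, reported with its line number."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One coded behavior interval for one individual."""

    individual: str
    behavior: str
    start_ms: int
    end_ms: int
    session_condition: str | None = None

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.end_ms < self.start_ms:
            raise ValueError("interval end must not precede its start")
        if self.session_condition is not None and self.session_condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.session_condition!r}")


def parse_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Parse a tab-delimited annotation export.

    Expected columns: individual, behavior, start_ms, end_ms and an
    optional condition.  A header line naming the first column
    ``individual`` is skipped.  Malformed lines raise
    :class:`AnnotationParseError` naming the offending line.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "individual":
                continue
            if len(parts) < 4:
                raise AnnotationParseError(f"line {lineno}: expected >= 4 fields")
            try:
                cond = parts[4].strip() if len(parts) > 4 and parts[4].strip() else None
                rec = AnnotationRecord(
                    individual=parts[0].strip(),
                    behavior=parts[1].strip(),
                    start_ms=int(parts[2]),
                    end_ms=int(parts[3]),
                    session_condition=cond,
                )
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


@dataclass
class BehaviorSummary:
    """Pilot-style summary: counts, proximity durations, totals, proportions."""

    counts: pd.DataFrame          # individuals x behaviors, event counts
    proximity_s: pd.Series        # per-individual proximity, seconds
    totals: pd.Series             # column sums over individuals
    total_proximity_s: float
    n_individuals: int
    condition_proportions: dict[str, float] | None = None


def condition_proportions(
    intervals: Sequence[tuple[str, int, int]], session_ms: int
) -> dict[str, float]:
    """Share of session time under each sound condition."""
    out: dict[str, float] = {}
    for cond, a, b in intervals:
        out[cond] = out.get(cond, 0.0) + (b - a) / session_ms
    return out


def summarize(
    records: Iterable[AnnotationRecord],
    condition_intervals: Sequence[tuple[str, int, int]] | None = None,
    session_ms: int | None = None,
) -> BehaviorSummary:
    """Aggregate annotation records into the pilot summary.

    Counts are per (individual, behavior); proximity seconds sum each
    individual's proximity intervals independently (overlap across
    individuals is allowed and expected).  If a condition schedule and
    session length are given, per-condition time proportions are added.
    """
    records = list(records)
    individuals = sorted({r.individual for r in records})
    counts = pd.DataFrame(0, index=individuals, columns=list(BEHAVIORS), dtype=int)
    prox_ms = pd.Series(0.0, index=individuals)
    for r in records:
        counts.loc[r.individual, r.behavior] += 1
        if r.behavior == "proximity":
            prox_ms[r.individual] += r.end_ms - r.start_ms
    proximity_s = prox_ms / 1000.0
    totals = counts.sum(axis=0)
    props = None
    if condition_intervals is not None and session_ms is not None:
        props = condition_proportions(condition_intervals, session_ms)
    return BehaviorSummary(
        counts=counts,
        proximity_s=proximity_s,
        totals=totals,
        total_proximity_s=float(proximity_s.sum()),
        n_individuals=len(individuals),
        condition_proportions=props,
    )


def merge_summaries(a: BehaviorSummary, b: BehaviorSummary) -> BehaviorSummary:
    """Combine two summaries; equals summarizing the concatenated records."""
    counts = a.counts.add(b.counts, fill_value=0).astype(int)
    counts = counts.sort_index()
    prox = a.proximity_s.add(b.proximity_s, fill_value=0.0).sort_index()
    return BehaviorSummary(
        counts=counts,
        proximity_s=prox,
        totals=counts.sum(axis=0),
        total_proximity_s=float(prox.sum()),
        n_individuals=len(counts.index),
        condition_proportions=None,
    )


def summary_table(summary: BehaviorSummary) -> pd.DataFrame:
    """Render the summary as the pilot table layout, with a totals row."""
    cols = ["proximity_s", "poke", "tool_use", "push", "hit", "display"]
    df = summary.counts[["poke", "tool_use", "push", "hit", "display"]].copy()
    df.insert(0, "proximity_s", summary.proximity_s)
    total = df.sum(axis=0)
    total.name = "Total"
    return pd.concat([df, total.to_frame().T])


def _condition_at(t_ms: int) -> str:
    for cond, a, b in PILOT_CONDITION_INTERVALS:
        if a <= t_ms < b:
            return cond
    return "none"


def write_pilot_fixture(path: str | Path) -> int:
    """Write the synthetic pilot-session annotation fixture; returns row count.

    The per-individual behavior counts, proximity durations and the
    sound-condition schedule match the pilot study's published summary
    table; the event *times* within the session are synthetic (the raw
    annotation timeline was never published).  Each individual gets one
    proximity interval of the recorded length, deterministically placed
    (overlaps across individuals occur, as they did in the session),
    with its point events spread evenly inside it.
    """
    rows: list[tuple[str, str, int, int, str]] = []
    for i, (name, (prox_s, poke, tool, push, hit, display)) in enumerate(
        PILOT_TABLE.items()
    ):
        prox_ms = prox_s * 1000
        span = PILOT_SESSION_MS - prox_ms
        t0 = (137_000 * (i + 1)) % max(span, 1)
        rows.append((name, "proximity", t0, t0 + prox_ms, _condition_at(t0)))
        events = (
            [("poke", poke), ("tool_use", tool), ("push", push),
             ("hit", hit), ("display", display)]
        )
        total_events = sum(n for _, n in events)
        k = 0
        for behavior, n in events:
            for _ in range(n):
                t = t0 + (k + 1) * prox_ms // (total_events + 1)
                rows.append((name, behavior, t, t, _condition_at(t)))
                k += 1
    rows.sort(key=lambda r: (r[2], r[0]))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual\tbehavior\tstart_ms\tend_ms\tcondition\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return len(rows)


def pilot_fixture_path() -> Path:
    """Path of the shipped synthetic pilot-session fixture."""
    return Path(resources.files("sonimotion").joinpath("data/pilot_session_synthetic.tsv"))
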