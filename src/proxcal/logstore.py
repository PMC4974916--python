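"""Encounter-log data model, CSV I/O and quality-control filtering.

Proximity-logger encounter logs arrive as CSV with the columns
``this.ID, enc.ID, first.time, last.time, RSSI.max, RSSI.min, RSSI.mean,
type``: receiver and transmitter tag identities, first/last pulse times
in 1/64-second "ticks", signal-strength statistics for the pulse
sequence, and an integer log-class code separating tag-to-tag logs from
error messages and controller commands.

Cleaning follows the calibration protocol: drop logs that are not
tag-to-tag communication, keep only single-pulse logs, and drop logs
recorded outside the trial time window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TAG_LOG_COLUMNS",
    "TagLog",
    "CleaningReport",
    "read_logs",
    "write_logs",
    "logs_to_frame",
    "ticks_to_seconds",
    "is_single_pulse",
    "clean_logs",
    "aggregate_pulses",
]

#: Exact header of the encounter-log CSV dialect.
TAG_LOG_COLUMNS: tuple[str, ...] = (
    "this.ID",
    "enc.ID",
    "first.time",
    "last.time",
    "RSSI.max",
    "RSSI.min",
    "RSSI.mean",
    "type",
)


@dataclass(frozen=True)
class TagLog:
    """One encounter-log record.

    Times are kept as exact integer ticks (1/64 s); ten-digit timestamps
    would lose precision as floats.  RSSI fields are dB.  A single-pulse
    log has identical min/mean/max RSSI and identical first/last times.
    """

    this_id: int
    enc_id: int
    first_time: int
    last_time: int
    rssi_max: float
    rssi_min: float
    rssi_mean: float
    type_code: int

    def __post_init__(self) -> None:
        if self.first_time > self.last_time:
            raise ValueError(
                f"first_time {self.first_time} > last_time {self.last_time}"
            )
        if not (self.rssi_min <= self.rssi_mean <= self.rssi_max):
            raise ValueError(
                "RSSI ordering violated: need min <= mean <= max, got "
                f"({self.rssi_min}, {self.rssi_mean}, {self.rssi_max})"
            )


@dataclass
class CleaningReport:
    """Tally of the quality-control filter, one count per removal rule.

    Each dropped record is charged to the first rule it fails, in the
    order non-tag -> multi-pulse -> outside-window, so the tally is
    deterministic and sums to the input size.
    """

    n_input: int = 0
    n_non_tag_removed: int = 0
    n_multi_pulse_removed: int = 0
    n_outside_window_removed: int = 0
    n_retained: int = 0
    notes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.notes is None:
            self.notes = []

    def validate(self) -> None:
        counts = (
            self.n_non_tag_removed,
            self.n_multi_pulse_removed,
            self.n_outside_window_removed,
            self.n_retained,
        )
        if any(c < 0 for c in counts) or self.n_input != sum(counts):
            raise ValueError(f"inconsistent cleaning tally: {self}")

    @property
    def fraction_non_tag(self) -> float:
        return self.n_non_tag_removed / self.n_input if self.n_input else 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _logs_from_frame(frame: pd.DataFrame, source: str = "<frame>") -> list[TagLog]:
    logs: list[TagLog] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            logs.append(
                TagLog(
                    this_id=int(row[0]),
                    enc_id=int(row[1]),
                    first_time=int(row[2]),
                    last_time=int(row[3]),
                    rssi_max=float(row[4]),
                    rssi_min=float(row[5]),
                    rssi_mean=float(row[6]),
                    type_code=int(row[7]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{source}: bad record at line {idx}: {exc}") from exc
    return logs


def read_logs(path: str | Path) -> list[TagLog]:
    """Read an encounter-log CSV; row order is preserved.

    Raises ``ValueError`` naming the column if the header deviates from
    the expected dialect, or naming the line if a cell fails to parse.
    Unicode minus signs (as they appear in printed tables) are accepted.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in TAG_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be "
                         f"{list(TAG_LOG_COLUMNS)}")
    frame = frame[list(TAG_LOG_COLUMNS)].apply(
        lambda col: col.str.replace("−", "-", regex=False)
    )
    return _logs_from_frame(frame, source=str(path))


def logs_to_frame(logs: Iterable[TagLog]) -> pd.DataFrame:
    """Render logs as a DataFrame in the CSV dialect's column layout."""
    rows = [
        (
            lg.this_id, lg.enc_id, lg.first_time, lg.last_time,
            lg.rssi_max, lg.rssi_min, lg.rssi_mean, lg.type_code,
        )
        for lg in logs
    ]
    return pd.DataFrame(rows, columns=list(TAG_LOG_COLUMNS))


def write_logs(logs: Iterable[TagLog], path: str | Path) -> None:
    """Write logs as CSV in the standard dialect (comma-separated, UTF-8)."""
    frame = logs_to_frame(logs)
    # RSSI columns print as integers when all values are whole, matching
    # the hardware's integer-dB output.
    for col in ("RSSI.max", "RSSI.min", "RSSI.mean"):
        if len(frame) and (frame[col] == frame[col].astype(int)).all():
            frame[col] = frame[col].astype(int)
    frame.to_csv(path, index=False)


def ticks_to_seconds(t) -> float:
    """Convert hardware ticks (1/64 s) to seconds, exactly t/64."""
    arr = np.asarray(t)
    if np.any(arr < 0):
        raise ValueError("tick times must be >= 0")
    out = arr / 64.0
    return float(out) if out.ndim == 0 else out


def is_single_pulse(log: TagLog) -> bool:
    """True iff the log represents exactly one received pulse.

    Single-pulse logs have identical min/mean/max RSSI and identical
    first/last times.  A multi-pulse log whose pulses happened to be
    identical is indistinguishable by this rule and will test true; the
    cleaning step flags that possibility in its report notes.
    """
    return (
        log.rssi_min == log.rssi_mean == log.rssi_max
        and log.first_time == log.last_time
    )


def clean_logs(
    logs: Sequence[TagLog],
    window: tuple[int, int],
    tag_type_codes: frozenset[int] | set[int] = frozenset({1}),
) -> tuple[list[TagLog], CleaningReport]:
    """Apply the three-stage quality-control filter.

    A log is retained iff, in order: its type code marks tag-to-tag
    communication; it is a single-pulse log; and its first pulse time
    falls inside ``window = (start, end)`` ticks, inclusive.  Each
    removal is tallied under the first failing rule.  Idempotent: the
    retained set passes a second application unchanged.
    """
    start, end = window
    if start > end:
        raise ValueError(f"window start {start} > end {end}")
    tag_type_codes = frozenset(tag_type_codes)

    report = CleaningReport(n_input=len(logs))
    retained: list[TagLog] = []
    for lg in logs:
        if lg.type_code not in tag_type_codes:
            report.n_non_tag_removed += 1
        elif not is_single_pulse(lg):
            report.n_multi_pulse_removed += 1
        elif not (start <= lg.first_time <= end):
            report.n_outside_window_removed += 1
        else:
            retained.append(lg)
    report.n_retained = len(retained)
    report.validate()
    return retained, report


def aggregate_pulses(
    logs: Sequence[TagLog], max_pulses: int
) -> list[TagLog]:
    """Summarise runs of single pulses into multi-pulse average logs.

    Emulates the tags' memory-saving firmware option: consecutive pulses
    for one directed pair are chunked into groups of at most
    ``max_pulses`` and each chunk is collapsed into one record carrying
    min/max/mean RSSI and the first/last pulse times.  Pulse count is
    conserved across chunks.
    """
    if max_pulses < 1:
        raise ValueError("max_pulses must be >= 1")
    if not logs:
        return []
    pair = (logs[0].this_id, logs[0].enc_id)
    prev_time = logs[0].first_time
    for lg in logs:
        if (lg.this_id, lg.enc_id) != pair:
            raise ValueError(
                f"mixed pair identities: {pair} vs {(lg.this_id, lg.enc_id)}"
            )
        if not is_single_pulse(lg):
            raise ValueError("aggregate_pulses requires single-pulse input logs")
        if lg.first_time < prev_time:
            raise ValueError("input logs must be sorted by time")
        prev_time = lg.first_time

    out: list[TagLog] = []
    for i in range(0, len(logs), max_pulses):
        chunk = logs[i : i + max_pulses]
        values = [lg.rssi_mean for lg in chunk]
        out.append(
            TagLog(
                this_id=pair[0],
                enc_id=pair[1],
                first_time=chunk[0].first_time,
                last_time=chunk[-1].last_time,
                rssi_max=max(values),
                rssi_min=min(values),
                rssi_mean=sum(values) / len(values),
                type_code=chunk[0].type_code,
            )
        )
    return out
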