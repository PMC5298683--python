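"""Trap event bookkeeping.

Each verified-or-not detection becomes a time-stamped, geo-tagged,
environment-annotated record in an append-only JSON Lines log — the
payload a field trap would queue for its scheduled uplink.  Snippets are
stored alongside as mono 16-bit WAV files, and daily reports aggregate
trigger and verification counts with an environment summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import numpy as np

from .wavio import write_wav


@dataclass(frozen=True)
class TrapEvent:
    """One detection record as transmitted by the trap."""

    timestamp: str  # ISO-8601, UTC
    latitude: float
    longitude: float
    temperature: float  # degC
    humidity: float  # %RH
    verified: bool
    snippet_ref: str
    rms_at_trigger: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")
        if not (0.0 <= self.humidity <= 100.0):
            raise ValueError(f"humidity {self.humidity} outside [0, 100] %RH")
        # Validate the timestamp is parseable ISO-8601.
        datetime.fromisoformat(self.timestamp)

    @property
    def utc_date(self) -> str:
        dt = datetime.fromisoformat(self.timestamp)
        if dt.tzinfo is not None:
            dt = dt.astimezone(timezone.utc)
        return dt.date().isoformat()


@dataclass(frozen=True)
class DailyReport:
    """Per-day aggregate the trap would uplink once per schedule."""

    date: str
    trap_id: str
    n_triggers: int
    n_verified: int
    temperature_min: float | None = None
    temperature_max: float | None = None
    humidity_min: float | None = None
    humidity_max: float | None = None

    def __post_init__(self) -> None:
        if self.n_verified > self.n_triggers:
            raise ValueError("n_verified cannot exceed n_triggers")


def append_event(log_path, event: TrapEvent) -> None:
    """Append one event as a JSON Lines record (append-only, replay-safe)."""
    with open(log_path, "a") as fh:
        fh.write(json.dumps(asdict(event)) + "\n")


def read_events(log_path) -> list[TrapEvent]:
    path = Path(log_path)
    if not path.exists():
        return []
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(TrapEvent(**json.loads(line)))
    return events


def daily_report(
    log: Iterable[TrapEvent] | str | Path, date: str, trap_id: str
) -> DailyReport:
    """Aggregate counts and environment extremes over one UTC date.

    An empty day yields zero counts with no environment summary.
    """
    events = read_events(log) if isinstance(log, (str, Path)) else list(log)
    day = [e for e in events if e.utc_date == date]
    if not day:
        return DailyReport(date=date, trap_id=trap_id, n_triggers=0, n_verified=0)
    temps = [e.temperature for e in day]
    hums = [e.humidity for e in day]
    return DailyReport(
        date=date,
        trap_id=trap_id,
        n_triggers=len(day),
        n_verified=sum(e.verified for e in day),
        temperature_min=min(temps),
        temperature_max=max(temps),
        humidity_min=min(hums),
        humidity_max=max(hums),
    )


def write_snippet(path, samples: np.ndarray, fs: int = 4000) -> str:
    """Store a snippet as mono PCM-16 WAV; returns the file reference.

    Out-of-range samples are clipped (with a warning) by the WAV writer;
    read-back agrees with the written samples to 16-bit quantisation.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) != 1024:
        raise ValueError("snippet must hold exactly 1024 samples")
    write_wav(path, samples, fs=fs)
    return str(path)
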