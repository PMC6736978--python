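"""Synchronized multi-rate time series and the on-disk session container.

All timestamps are seconds from session start. A :class:`SessionRecording`
bundles the force-plate wrenches, arm-rail force triplets, marker
trajectories and the stimulation envelope on one uniform time grid
(default 100 Hz), together with participant metadata and an event log.

On disk a recording is a directory with a ``session.json`` sidecar
(metadata, masses, grid rate, events, stream manifest) plus one
comma-separated table per stream whose first column is time and whose
header row carries the channel labels. The format is deliberately plain
text so fixtures can be inspected and diffed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError, SpanError

#: Controlled vocabulary for event labels.
EVENT_LABELS = frozenset(
    {"stand_start", "exercise_start", "rest_start", "rest_end", "sit_start"}
)

#: Decimal places preserved by the container round-trip.
VALUE_DECIMALS = 6


@dataclass
class TimedStream:
    """One named multi-channel time series with strictly increasing timestamps."""

    name: str
    channel_labels: list[str]
    timestamps: np.ndarray
    values: np.ndarray
    units: list[str]
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.timestamps.ndim != 1:
            raise DataError(f"stream {self.name!r}: timestamps must be 1-D")
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise DataError(
                f"stream {self.name!r}: {self.values.shape[0]} rows for "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.values.shape[1] != len(self.channel_labels):
            raise DataError(
                f"stream {self.name!r}: {self.values.shape[1]} columns for "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(self.units) != len(self.channel_labels):
            raise DataError(f"stream {self.name!r}: one unit tag per channel required")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise DataError(f"stream {self.name!r}: timestamps must strictly increase")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        try:
            i = self.channel_labels.index(label)
        except ValueError as exc:
            raise DataError(f"stream {self.name!r} has no channel {label!r}") from exc
        return self.values[:, i]

    def select(self, label: str) -> "TimedStream":
        """Return a single-channel view of this stream as a new TimedStream."""
        i = self.channel_labels.index(label)
        return TimedStream(
            name=f"{self.name}.{label}",
            channel_labels=[label],
            timestamps=self.timestamps,
            values=self.values[:, i : i + 1],
            units=[self.units[i]],
            nominal_rate=self.nominal_rate,
        )


@dataclass
class EventLog:
    """Timestamped session events with a documented label vocabulary."""

    entries: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise DataError("event timestamps must be non-decreasing")
        for _, label in self.entries:
            if label not in EVENT_LABELS:
                raise DataError(f"unknown event label {label!r}")

    def first(self, label: str) -> float | None:
        for t, lab in self.entries:
            if lab == label:
                return t
        return None

    def exclusion_intervals(self, t_end: float) -> list[tuple[float, float]]:
        """Non-exercise intervals: before exercise_start, rest periods, after sit_start.

        Used by the analysis stage to drop transfer/rest peaks deterministically.
        """
        out: list[tuple[float, float]] = []
        ex = self.first("exercise_start")
        if ex is not None:
            out.append((-np.inf, ex))
        rest_open: float | None = None
        for t, lab in self.entries:
            if lab == "rest_start":
                rest_open = t
            elif lab == "rest_end" and rest_open is not None:
                out.append((rest_open, t))
                rest_open = None
        if rest_open is not None:
            out.append((rest_open, t_end))
        sit = self.first("sit_start")
        if sit is not None:
            out.append((sit, np.inf))
        return out


@dataclass
class SessionRecording:
    """A fully synchronized session: streams, events and participant metadata."""

    participant_id: str
    session_index: int
    body_mass: float
    wheelchair_mass: float
    streams: dict[str, TimedStream]
    events: EventLog
    grid_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise DataError("body_mass must be positive")
        if self.session_index < 1:
            raise DataError("session_index must be a positive integer")
        grids = [s.timestamps for s in self.streams.values()]
        for g in grids[1:]:
            if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
                raise DataError("all streams must share one uniform time grid")

    @property
    def time(self) -> np.ndarray:
        return next(iter(self.streams.values())).timestamps

    @property
    def span(self) -> tuple[float, float]:
        t = self.time
        return float(t[0]), float(t[-1])


def resample_to_grid(stream: TimedStream, rate: float, t0: float, t1: float) -> TimedStream:
    """Linearly interpolate a stream onto a uniform grid over ``[t0, t1]``.

    The grid runs from ``t0`` at spacing ``1/rate`` up to the last point not
    beyond ``t1`` (within a half-sample tolerance); no extrapolation occurs.
    """
    if stream.n_samples < 2:
        raise DataError(f"stream {stream.name!r}: need at least 2 samples to resample")
    lo, hi = stream.span
    eps = 0.5 / rate * 1e-6
    if t0 < lo - eps or t1 > hi + eps or t1 < t0:
        raise SpanError(
            f"requested [{t0}, {t1}] outside stream {stream.name!r} span [{lo}, {hi}]"
        )
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    grid = np.clip(grid, lo, hi)  # guard fp rounding at the edges
    out = np.empty((n, stream.values.shape[1]))
    for j in range(stream.values.shape[1]):
        out[:, j] = np.interp(grid, stream.timestamps, stream.values[:, j])
    return TimedStream(
        name=stream.name,
        channel_labels=list(stream.channel_labels),
        timestamps=t0 + np.arange(n) / rate,
        values=out,
        units=list(stream.units),
        nominal_rate=rate,
    )


def synchronize(streams: Iterable[TimedStream], rate: float) -> dict[str, TimedStream]:
    """Resample every stream onto the common grid spanned by all of them.

    The common grid is the intersection of the individual spans sampled at
    ``rate``; a stream never contributes samples outside its own span.
    """
    streams = list(streams)
    if not streams:
        raise AlignmentError("no streams to synchronize")
    t0 = max(s.span[0] for s in streams)
    t1 = min(s.span[1] for s in streams)
    if t1 < t0:
        raise AlignmentError(f"streams have no overlapping span ({t0} > {t1})")
    return {s.name: resample_to_grid(s, rate, t0, t1) for s in streams}


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_SIDECAR = "session.json"


def write_session(rec: SessionRecording, path: str | Path) -> None:
    """Write a recording as a directory of CSV stream tables + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, stream in rec.streams.items():
        fname = f"{name}.csv"
        df = pd.DataFrame(
            np.round(stream.values, VALUE_DECIMALS), columns=stream.channel_labels
        )
        df.insert(0, "time", np.round(stream.timestamps, VALUE_DECIMALS))
        df.to_csv(path / fname, index=False, float_format=f"%.{VALUE_DECIMALS}f")
        manifest[name] = {
            "file": fname,
            "channels": list(stream.channel_labels),
            "units": list(stream.units),
            "nominal_rate": stream.nominal_rate,
        }
    sidecar = {
        "participant_id": rec.participant_id,
        "session_index": rec.session_index,
        "body_mass": rec.body_mass,
        "wheelchair_mass": rec.wheelchair_mass,
        "grid_rate": rec.grid_rate,
        "events": [[t, lab] for t, lab in rec.events.entries],
        "streams": manifest,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))


def read_session(path: str | Path) -> SessionRecording:
    """Read a session container written by :func:`write_session`."""
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {_SIDECAR!r} in {path}")
    meta = json.loads(sidecar_path.read_text())
    streams: dict[str, TimedStream] = {}
    for name, entry in meta["streams"].items():
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FormatError(f"missing stream file {entry['file']!r} in {path}")
        df = pd.read_csv(fpath)
        streams[name] = TimedStream(
            name=name,
            channel_labels=list(entry["channels"]),
            timestamps=df["time"].to_numpy(),
            values=df[entry["channels"]].to_numpy(),
            units=list(entry["units"]),
            nominal_rate=float(entry["nominal_rate"]),
        )
    return SessionRecording(
        participant_id=meta["participant_id"],
        session_index=int(meta["session_index"]),
        body_mass=float(meta["body_mass"]),
        wheelchair_mass=float(meta["wheelchair_mass"]),
        streams=streams,
        events=EventLog([(float(t), str(lab)) for t, lab in meta["events"]]),
        grid_rate=float(meta["grid_rate"]),
    )
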