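"""Cyclic posture-shifting FES pattern generator and pulse-train synthesis.

The stimulator drives two muscle groups (LEFT and RIGHT lower limb) with a
periodic envelope built from four timing parameters: ON time (full
stimulation plateau), OFF time (rest plateau), transition time (linear ramp
between the two) and the OFF-stimulation percentage (rest level as a
fraction of the ON level). The RIGHT group runs the same envelope shifted
by half a period, so with ``on_time == off_time + 2*transition_time`` the
two groups' plateaus tile: one side is always fully stimulated except
during the crossing ramps. Time zero is the start of the LEFT ON plateau.

The envelope modulates pulse *width*; the pulse amplitude (138 mA into a
nominal 1 kOhm || 100 nF load) and the 30 Hz pulse rate are fixed device
properties carried as metadata. Pulses are represented as discrete
(time, width, amplitude) events rather than sampled waveforms.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

#: Fixed device pulse rate, Hz.
PULSE_FREQUENCY_HZ = 30.0
#: Fixed device pulse amplitude, mA (into a nominal 1 kOhm || 100 nF load).
PULSE_AMPLITUDE_MA = 138.0
#: Upper limit of the adjustable pulse width, microseconds.
MAX_PULSE_WIDTH_US = 500.0
#: Number of output channels on the device.
N_CHANNELS = 16


class Group(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    UNASSIGNED = "UNASSIGNED"


def _default_channel_group() -> dict[int, Group]:
    # channels 1-8 left limb muscles, 9-16 right limb muscles
    return {ch: (Group.LEFT if ch <= 8 else Group.RIGHT) for ch in range(1, N_CHANNELS + 1)}


def _default_pulse_widths() -> dict[int, float]:
    return {ch: 300.0 for ch in range(1, N_CHANNELS + 1)}


@dataclass
class StimSchedule:
    """Timing/level parameters and channel-group map for the cyclic pattern.

    Defaults are the exercise-protocol settings: 5 s ON, 3 s OFF, 1 s
    transitions (a tiling pattern with a 10 s period) and no stimulation of
    the resting side.
    """

    on_time: float = 5.0
    off_time: float = 3.0
    transition_time: float = 1.0
    off_pct: float = 0.0
    frequency: float = PULSE_FREQUENCY_HZ
    amplitude_ma: float = PULSE_AMPLITUDE_MA
    channel_group: dict[int, Group] = field(default_factory=_default_channel_group)
    on_pulse_width: dict[int, float] = field(default_factory=_default_pulse_widths)

    def __post_init__(self) -> None:
        if min(self.on_time, self.off_time, self.transition_time) <= 0:
            raise ConfigurationError("on/off/transition times must all be positive")
        if not 0.0 <= self.off_pct <= 1.0:
            raise ConfigurationError("off_pct must lie in [0, 1]")
        for ch, w in self.on_pulse_width.items():
            if not 0.0 <= w <= MAX_PULSE_WIDTH_US:
                raise ConfigurationError(
                    f"channel {ch}: pulse width {w} outside [0, {MAX_PULSE_WIDTH_US}] us"
                )
        self.channel_group = {ch: Group(g) for ch, g in self.channel_group.items()}
        for grp in (Group.LEFT, Group.RIGHT):
            if self.channels_in(grp):
                break
        else:
            raise ConfigurationError("at least one channel must be assigned to a group")

    @property
    def period(self) -> float:
        return self.on_time + self.off_time + 2.0 * self.transition_time

    def channels_in(self, group: Group) -> list[int]:
        return [ch for ch, g in self.channel_group.items() if g == group]

    # -- config I/O ---------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "StimSchedule":
        d = dict(d)
        if "channel_group" in d:
            d["channel_group"] = {int(k): Group(v) for k, v in d["channel_group"].items()}
        if "on_pulse_width" in d:
            d["on_pulse_width"] = {int(k): float(v) for k, v in d["on_pulse_width"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StimSchedule":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "on_time": self.on_time,
            "off_time": self.off_time,
            "transition_time": self.transition_time,
            "off_pct": self.off_pct,
            "frequency": self.frequency,
            "amplitude_ma": self.amplitude_ma,
            "channel_group": {ch: g.value for ch, g in self.channel_group.items()},
            "on_pulse_width": dict(self.on_pulse_width),
        }


@dataclass
class PulseTrain:
    """Discrete stimulation pulses on one channel."""

    pulse_times: np.ndarray
    pulse_widths: np.ndarray
    amplitude_ma: float = PULSE_AMPLITUDE_MA

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.pulse_widths = np.asarray(self.pulse_widths, dtype=float)

    def __len__(self) -> int:
        return self.pulse_times.shape[0]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.pulse_times,
                "width_us": self.pulse_widths,
                "amplitude_ma": self.amplitude_ma,
            }
        )


def envelope_level(sched: StimSchedule, group: Group | str, t) -> np.ndarray | float:
    """Envelope level in ``[off_pct, 1]`` for a group at time(s) ``t``.

    One period of the LEFT group is: ON plateau -> linear ramp down -> OFF
    plateau at ``off_pct`` -> linear ramp up. RIGHT is LEFT delayed by half
    a period. Continuous at every plateau/ramp boundary.
    """
    group = Group(group)
    if group == Group.UNASSIGNED:
        raise ConfigurationError("cannot query the envelope of an unassigned group")
    t = np.asarray(t, dtype=float)
    P = sched.period
    shift = 0.0 if group == Group.LEFT else P / 2.0
    u = np.mod(t - shift, P)
    on, tr, off = sched.on_time, sched.transition_time, sched.off_pct
    span = 1.0 - off
    level = np.where(
        u < on,
        1.0,
        np.where(
            u < on + tr,
            1.0 - span * (u - on) / tr,
            np.where(
                u < on + tr + sched.off_time,
                off,
                off + span * (u - (on + tr + sched.off_time)) / tr,
            ),
        ),
    )
    return level if level.ndim else float(level)


@dataclass
class ScheduleReport:
    """Geometry report for a schedule: period and plateau-tiling diagnosis."""

    period: float
    classification: str  # "tiling", "overlap" or "gap"
    mismatch: float  # seconds of overlap (>0) or gap (<0); 0 when tiling


def validate_schedule(sched: StimSchedule) -> ScheduleReport:
    """Report the period and whether opposite ON plateaus tile, overlap or gap.

    The two groups' ON plateaus exactly alternate ("tiling") when
    ``on_time == off_time + 2 * transition_time``.
    """
    delta = sched.on_time - (sched.off_time + 2.0 * sched.transition_time)
    if abs(delta) < 1e-12:
        cls = "tiling"
    elif delta > 0:
        cls = "overlap"
    else:
        cls = "gap"
    return ScheduleReport(period=sched.period, classification=cls, mismatch=delta)


def generate_pulse_train(
    sched: StimSchedule, channel: int, t0: float, t1: float
) -> PulseTrain:
    """Synthesize the pulse events for one channel over ``[t0, t1)``.

    Pulses fall at ``t0 + k/frequency``; each pulse's width is the channel's
    ON pulse width scaled by the envelope at that instant. Zero-width pulses
    are omitted.
    """
    if t0 >= t1:
        raise ConfigurationError("generate_pulse_train requires t0 < t1")
    group = sched.channel_group.get(channel, Group.UNASSIGNED)
    if group == Group.UNASSIGNED:
        raise ConfigurationError(f"channel {channel} is not assigned to a group")
    n = int(np.ceil((t1 - t0) * sched.frequency - 1e-9))
    times = t0 + np.arange(n) / sched.frequency
    widths = np.asarray(envelope_level(sched, group, times)) * sched.on_pulse_width[channel]
    keep = widths > 0
    return PulseTrain(times[keep], widths[keep], sched.amplitude_ma)


@dataclass
class StimProgram:
    """A session's stimulation program: continuous hold, then the cyclic pattern.

    During stand-up the operator applies a constant level to selected
    channels; when the participant is stable the output switches to the
    cyclic pattern. The switch is pinned to a LEFT-ON plateau start, where
    both group envelopes equal 1, so a full-level hold hands over without a
    level discontinuity.
    """

    schedule: StimSchedule
    continuous_level: float = 1.0
    switch_time: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.continuous_level <= 1.0:
            raise ConfigurationError("continuous level must lie in [0, 1]")

    def envelope(self, group: Group | str, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cyclic = np.asarray(envelope_level(self.schedule, group, t - self.switch_time))
        return np.where(t < self.switch_time, self.continuous_level, cyclic)


def continuous_mode(level: float, channels: list[int]) -> dict[int, float]:
    """Constant envelope at ``level`` on the listed channels (stand-up assist)."""
    if not 0.0 <= level <= 1.0:
        raise ConfigurationError("continuous level must lie in [0, 1]")
    return {ch: level for ch in channels}


def next_plateau_start(sched: StimSchedule, after: float) -> float:
    """First LEFT-ON plateau start at or after ``after`` (a multiple of the period)."""
    P = sched.period
    return float(np.ceil(after / P - 1e-12) * P)


def rasterize_envelope(
    sched: StimSchedule, group: Group | str, rate: float, t0: float, t1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the envelope on a uniform grid (plotting/test helper)."""
    n = int(np.floor((t1 - t0) * rate)) + 1
    t = t0 + np.arange(n) / rate
    return t, np.asarray(envelope_level(sched, group, t))
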