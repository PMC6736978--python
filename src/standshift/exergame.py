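"""Rendering-free skiing-exergame feedback logic.

The virtual skier's horizontal position is the normalized left/right
weight-distribution imbalance; hoops appear on the stimulated side once
per ON plateau and are scored when the skier is within a band of the hoop
centre at hoop time. An arm-force warning fires when the rails carry more
than a threshold share of body weight. No graphics: the module emits
plain state records for logging and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .stimulation import StimSchedule

#: Hoop centres on the normalized slope, per side.
HOOP_TARGET = {"L": -0.5, "R": +0.5}
#: Default scoring band half-width around the hoop centre.
SCORE_BAND = 0.25
#: Default excessive-arm-force threshold, % body weight.
ARM_WARNING_THRESHOLD_BW = 10.0


def skier_position(fz_left: float, fz_right: float) -> float:
    """Normalized imbalance ``(Fz_right - Fz_left)/(Fz_right + Fz_left)`` in [-1, 1].

    Positive values move the skier toward the participant's right.
    """
    fz_left = np.asarray(fz_left, dtype=float)
    fz_right = np.asarray(fz_right, dtype=float)
    total = fz_left + fz_right
    if np.any(total <= 0):
        raise DataError("skier position undefined for non-positive total leg force")
    out = np.clip((fz_right - fz_left) / total, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Hoop:
    side: str  # "L" or "R"
    time: float  # s, when the skier reaches the hoop


@dataclass
class GameState:
    skier_x: float = 0.0
    score: int = 0
    arm_warning: bool = False
    hoops: list[Hoop] = field(default_factory=list)


def hoop_schedule(sched: StimSchedule, duration: float) -> list[Hoop]:
    """One hoop per ON plateau starting within ``duration``, at the plateau midpoint.

    Sides alternate with the stimulation: LEFT plateaus start at multiples
    of the period, RIGHT plateaus half a period later.
    """
    P = sched.period
    mid = sched.on_time / 2.0
    hoops = []
    k = 0
    while True:
        start_l, start_r = k * P, k * P + P / 2.0
        if start_l >= duration and start_r >= duration:
            break
        if start_l < duration:
            hoops.append(Hoop("L", start_l + mid))
        if start_r < duration:
            hoops.append(Hoop("R", start_r + mid))
        k += 1
    return hoops


def update_game(
    state: GameState, skier_x: float, hoop: Hoop, band: float = SCORE_BAND
) -> GameState:
    """Score a hoop: a point iff the skier is within ``band`` of the hoop centre."""
    scored = abs(skier_x - HOOP_TARGET[hoop.side]) <= band
    return replace(state, skier_x=skier_x, score=state.score + int(scored))


def arm_warning(
    arm_bw_pct: float, threshold: float = ARM_WARNING_THRESHOLD_BW
) -> bool:
    """True iff the arm-force magnitude strictly exceeds ``threshold`` % BW."""
    return float(arm_bw_pct) > threshold


def play_session(rec, sched: StimSchedule, band: float = SCORE_BAND) -> pd.DataFrame:
    """Replay a recording through the game logic: one row per hoop.

    Hoop times are laid out from the ``exercise_start`` event; skier
    position and arm warning are evaluated from the recorded forces at
    each hoop time.
    """
    from .analysis import to_bw_percent
    from .streams import SessionRecording  # noqa: F401  (type context)

    t_ex = rec.events.first("exercise_start") or 0.0
    t_end = rec.span[1]
    hoops = [h for h in hoop_schedule(sched, t_end - t_ex)]
    state = GameState(hoops=list(hoops))
    rows = []
    for hoop in hoops:
        t = t_ex + hoop.time
        if t > t_end:
            break
        fzl = np.interp(t, rec.streams["plate_left"].timestamps, rec.streams["plate_left"].channel("Fz"))
        fzr = np.interp(t, rec.streams["plate_right"].timestamps, rec.streams["plate_right"].channel("Fz"))
        arm = np.interp(t, rec.streams["rail_left"].timestamps, rec.streams["rail_left"].channel("Fz")) + np.interp(
            t, rec.streams["rail_right"].timestamps, rec.streams["rail_right"].channel("Fz")
        )
        x = skier_position(fzl, fzr)
        prev_score = state.score
        state = update_game(state, x, hoop, band=band)
        rows.append(
            {
                "time_s": t,
                "side": hoop.side,
                "skier_x": x,
                "scored": state.score > prev_score,
                "score": state.score,
                "arm_warning": arm_warning(abs(float(to_bw_percent(arm, rec.body_mass)))),
            }
        )
    return pd.DataFrame(rows)
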