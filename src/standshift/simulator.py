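"""Virtual participant + frame: synthesizes complete exercise sessions.

The simulator replaces the human and the hardware for desk-scale testing.
It is behavioural, not musculoskeletal: the exergame-guided weight shift is
modelled as a first-order lag of a drive signal derived from the
stimulation envelope, with a brief "commitment surge" at each hoop time
(participants push their lean hardest as the hoop arrives), a habituation
ramp at the start of each session, and cycle-to-cycle and session-to-
session variability.

Per sample, the two plates' vertical forces, the rail forces and a small
knee-pad/harness residual partition body weight exactly before noise.
Sensor noise is added last: band-limited Gaussian noise on forces and
markers (adjacent 100 Hz samples are correlated, as after an acquisition
anti-alias chain). The sensing-module calibrations sit in the loop: the
physical wrenches are converted to raw sensor units and back through the
plate matrices and rail calibrations before being recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .errors import ConfigurationError
from .sensing import (
    GRAVITY,
    LinearCalibration,
    PlateCalibration,
    RailCalibration,
    apply_plate_matrix,
    pair_average,
)
from .stimulation import Group, StimProgram, StimSchedule
from .streams import EventLog, SessionRecording, TimedStream

#: Default supplier-style plate calibration matrix: per-channel gains with
#: small cross-talk terms (raw volts -> N / N*m).
DEFAULT_PLATE_MATRIX = np.array(
    [
        [500.0, 2.0, -1.5, 0.0, 0.3, 0.0],
        [1.8, 500.0, 2.2, -0.2, 0.0, 0.1],
        [-2.5, 1.2, 1000.0, 0.4, -0.3, 0.0],
        [0.0, -0.1, 0.2, 400.0, 1.0, 0.5],
        [0.1, 0.0, -0.4, 0.8, 400.0, 0.2],
        [0.0, 0.1, 0.0, 0.3, -0.2, 200.0],
    ]
)

#: Default rail per-DoF calibration (raw bridge counts -> N).
def default_rail_calibration() -> RailCalibration:
    return RailCalibration(
        {
            "Fx": LinearCalibration(gain=0.251, offset=-3.2),
            "Fy": LinearCalibration(gain=0.249, offset=1.1),
            "Fz": LinearCalibration(gain=0.247, offset=-8.5),
        }
    )


@dataclass
class ImprovementProfile:
    """Longitudinal improvement of the session-level support fraction.

    Session 1 sits at ``early``; a small drift over the first five sessions
    models familiarization; support then rises linearly and saturates at
    ``late`` from ``saturation_session`` on.
    """

    early: float = 0.6369
    late: float = 0.7861
    early_drift: float = 0.0026  # per-session drift within the early block
    n_early: int = 5
    saturation_session: int = 8

    def fraction_of_gain(self, session_index: int) -> float:
        """Normalized position in [0, 1] between early and late levels."""
        if session_index < 1:
            raise ConfigurationError("session_index must be >= 1")
        gain = self.late - self.early
        drift = self.early_drift / gain if gain > 0 else 0.0
        k_early = self.n_early
        psi_early_end = drift * (k_early - 1)
        if session_index <= k_early:
            return drift * (session_index - 1)
        if session_index >= self.saturation_session:
            return 1.0
        frac = (session_index - k_early) / (self.saturation_session - k_early)
        return psi_early_end + (1.0 - psi_early_end) * frac

    def at(self, session_index: int) -> float:
        return self.early + (self.late - self.early) * self.fraction_of_gain(session_index)


@dataclass
class VirtualParticipant:
    """Masses, support fractions and behavioural parameters of one simulated user.

    Fractions are of body weight. ``mature_support_frac`` is the
    supporting-leg share at the lean apex once performance has stabilized;
    ``arm_support_frac`` the share carried through the rails;
    ``residual_frac`` the knee-pad/harness share. The off-side leg carries
    the remainder, so both legs together carry
    ``1 - arm_support_frac - residual_frac`` (~90% BW).
    """

    participant_id: str = "P1"
    body_mass: float = 83.3
    wheelchair_mass: float = 16.7
    mature_support_frac: float = 0.7532
    arm_support_frac: float = 0.0759
    arm_strategy: str = "push"  # "push" (rails loaded downward) or "pull"
    residual_frac: float = 0.0241
    habituation: float = 300.0  # s of within-session ramp-in
    habituation_shape: float = 3.0  # ramp convexity; >1 = slow start, fast finish
    response_lag: float = 0.4  # s, first-order tracking of the envelope
    improvement: ImprovementProfile = field(default_factory=ImprovementProfile)
    sway_early_deg: float = 6.065  # clavicle half-angle, early sessions
    sway_late_deg: float = 7.61
    clavicle_height: float = 1.35  # m above the plate surface
    force_noise_sd: float = 5.0  # N, per force channel
    marker_noise_sd: float = 0.002  # m, per marker coordinate
    noise_correlation_s: float = 0.03  # Gaussian smoothing width of the noise
    surge_depth: float = 0.15  # drive units; apex height above the held lean
    surge_half_width: float = 0.4  # s, raised-cosine half-width of the surge
    cycle_jitter_sd: float = 0.065  # relative amplitude SD per half-cycle
    session_jitter_sd: float = 0.005  # SD of the session support level (BW frac)

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ConfigurationError("body mass must be positive")
        for name in ("mature_support_frac", "arm_support_frac", "residual_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.mature_support_frac + self.arm_support_frac + self.residual_frac > 1.0:
            raise ConfigurationError("support + arm + residual fractions exceed body weight")
        if self.mature_support_frac > self.legs_total_frac:
            raise ConfigurationError("supporting-leg fraction exceeds total leg share")
        if self.arm_strategy not in ("push", "pull"):
            raise ConfigurationError("arm_strategy must be 'push' or 'pull'")

    @property
    def legs_total_frac(self) -> float:
        return 1.0 - self.arm_support_frac - self.residual_frac

    def sway_for_session(self, session_index: int | None) -> float:
        if session_index is None:
            return self.sway_late_deg
        frac = self.improvement.fraction_of_gain(session_index)
        return self.sway_early_deg + (self.sway_late_deg - self.sway_early_deg) * frac


@dataclass
class SimConfig:
    """One simulated session's run parameters."""

    seed: int
    duration: float = 3600.0
    grid_rate: float = 100.0
    schedule: StimSchedule = field(default_factory=StimSchedule)
    session_index: int | None = None  # None -> mature single-session profile
    stand_lead: float = 10.0  # s of centered standing before the cyclic pattern

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")


def participant_profile(p: VirtualParticipant, session_index: int) -> float:
    """Session-level supporting-leg fraction: monotone early->late, saturating."""
    return p.improvement.at(session_index)


def _band_limited_noise(rng, shape, sd: float, sigma_samples: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if sigma_samples <= 0 or sd == 0:
        return sd * white
    smooth = gaussian_filter1d(white, sigma_samples, axis=0)
    # restore unit marginal variance (kernel energy ~ 1/(2*sigma*sqrt(pi)))
    smooth *= np.sqrt(2.0 * sigma_samples * np.sqrt(np.pi))
    return sd * smooth


def _drive_signal(p: VirtualParticipant, cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Normalized lean drives in [-1, 1] (+1 = full lean onto the left leg).

    Returns ``(force_drive, posture_drive)``: the force drive carries the
    commitment surge at each hoop, while the posture (trunk sway) drive
    holds the plateau — participants maintain a stable lean through the ON
    period while the extra force at the hoop is dynamic.
    """
    sched = cfg.schedule
    dt = 1.0 / cfg.grid_rate
    n = int(round(cfg.duration * cfg.grid_rate))
    t = np.arange(n) * dt
    te = t - cfg.stand_lead

    from .stimulation import envelope_level

    diff = np.where(
        te >= 0,
        np.asarray(envelope_level(sched, Group.LEFT, np.maximum(te, 0.0)))
        - np.asarray(envelope_level(sched, Group.RIGHT, np.maximum(te, 0.0))),
        0.0,
    )
    alpha = dt / (p.response_lag + dt)
    lagged = lfilter([alpha], [1.0, -(1.0 - alpha)], diff)

    P = sched.period
    u = np.mod(te, P)
    ws = p.surge_half_width
    mid_l = sched.on_time / 2.0
    mid_r = P / 2.0 + sched.on_time / 2.0
    bump_l = np.where(np.abs(u - mid_l) <= ws, 0.5 * (1 + np.cos(np.pi * (u - mid_l) / ws)), 0.0)
    bump_r = np.where(np.abs(u - mid_r) <= ws, 0.5 * (1 + np.cos(np.pi * (u - mid_r) / ws)), 0.0)
    bumps = np.where(te >= 0, bump_l - bump_r, 0.0)

    w_force = (1.0 - p.surge_depth) * lagged + p.surge_depth * bumps

    # habituation: amplitude grows from zero to full over `habituation` seconds,
    # slowly at first (early leans stay below the detection threshold)
    if p.habituation > 0:
        ramp = np.clip(te / p.habituation, 0.0, 1.0) ** p.habituation_shape
    else:
        ramp = np.ones_like(te)

    # per-half-cycle amplitude variability
    half = P / 2.0
    n_cycles = int(np.floor(cfg.duration / half)) + 2
    jitter = rng.normal(0.0, p.cycle_jitter_sd, n_cycles)
    ci = np.clip(np.floor(np.maximum(te, 0.0) / half).astype(int), 0, n_cycles - 1)
    amp = ramp * (1.0 + jitter[ci])
    return w_force * amp, lagged * amp


def simulate_session(p: VirtualParticipant, cfg: SimConfig) -> SessionRecording:
    """Generate one fully synchronized, physically consistent session recording.

    Vertical forces partition body weight exactly before noise:
    ``Fz_left + Fz_right + |Fz_arms| + residual = body_mass * g`` at every
    sample. The clavicle marker swings on an inverted pendulum of length
    ``clavicle_height`` following the same drive as the leg imbalance.
    """
    rng = np.random.default_rng(cfg.seed)
    sched = cfg.schedule
    dt = 1.0 / cfg.grid_rate
    n = int(round(cfg.duration * cfg.grid_rate))
    t = np.arange(n) * dt
    mg = p.body_mass * GRAVITY

    # session-level support fraction (mature, or from the improvement profile)
    if cfg.session_index is None:
        s_level = p.mature_support_frac
    else:
        s_level = participant_profile(p, cfg.session_index)
    s_sess = min(s_level + rng.normal(0.0, p.session_jitter_sd), p.legs_total_frac)
    sway_deg = p.sway_for_session(cfg.session_index)

    w_force, w_sway = _drive_signal(p, cfg, rng)

    legs = p.legs_total_frac
    center = legs / 2.0
    share_l = center + (s_sess - center) * w_force
    fz_l = share_l * mg
    fz_r = (legs - share_l) * mg

    arm_sign = 1.0 if p.arm_strategy == "push" else -1.0
    rail_fz = arm_sign * p.arm_support_frac * mg / 2.0  # per rail

    theta = -np.deg2rad(sway_deg) * w_sway  # X positive toward the participant's right
    clav = np.column_stack(
        [
            p.clavicle_height * np.sin(theta),
            np.full(n, 0.10),
            p.clavicle_height * np.cos(theta),
        ]
    )

    # --- pass the physical signals through the sensing chain ---------------
    plate_cal = PlateCalibration(DEFAULT_PLATE_MATRIX)
    inv = plate_cal.inverse()
    rail_cal = default_rail_calibration()

    def plate_stream(name: str, fz: np.ndarray) -> TimedStream:
        wrench = np.zeros((n, 6))
        wrench[:, 2] = fz
        raw = wrench @ inv.T  # what the amplifier would have output
        calibrated = apply_plate_matrix(raw, plate_cal)
        noise = np.column_stack(
            [
                _band_limited_noise(
                    rng,
                    n,
                    p.force_noise_sd if j < 3 else 0.2 * p.force_noise_sd,
                    p.noise_correlation_s * cfg.grid_rate,
                )
                for j in range(6)
            ]
        )
        return TimedStream(
            name=name,
            channel_labels=["Fx", "Fy", "Fz", "Mx", "My", "Mz"],
            timestamps=t,
            values=calibrated + noise,
            units=["N", "N", "N", "N*m", "N*m", "N*m"],
            nominal_rate=cfg.grid_rate,
        )

    def rail_stream(name: str) -> TimedStream:
        force = np.zeros((n, 3))
        force[:, 2] = rail_fz
        # each DoF is read by two co-planar cells with opposite static offsets
        raw_dof = np.column_stack(
            [rail_cal.axes[k].invert(force[:, i]) for i, k in enumerate(("Fx", "Fy", "Fz"))]
        )
        cell_offsets = np.array([4.0, -2.5, 7.0])
        raw_avg = pair_average(raw_dof + cell_offsets, raw_dof - cell_offsets)
        calibrated = rail_cal.apply(raw_avg)
        noise = np.column_stack(
            [
                _band_limited_noise(rng, n, p.force_noise_sd, p.noise_correlation_s * cfg.grid_rate)
                for _ in range(3)
            ]
        )
        return TimedStream(
            name=name,
            channel_labels=["Fx", "Fy", "Fz"],
            timestamps=t,
            values=calibrated + noise,
            units=["N", "N", "N"],
            nominal_rate=cfg.grid_rate,
        )

    program = StimProgram(schedule=sched, continuous_level=1.0, switch_time=cfg.stand_lead)
    env = np.column_stack(
        [program.envelope(Group.LEFT, t), program.envelope(Group.RIGHT, t)]
    )

    marker_noise = np.column_stack(
        [
            _band_limited_noise(rng, n, p.marker_noise_sd, p.noise_correlation_s * cfg.grid_rate)
            for _ in range(3)
        ]
    )

    streams = {
        "plate_left": plate_stream("plate_left", fz_l),
        "plate_right": plate_stream("plate_right", fz_r),
        "rail_left": rail_stream("rail_left"),
        "rail_right": rail_stream("rail_right"),
        "markers": TimedStream(
            name="markers",
            channel_labels=["clavicle_x", "clavicle_y", "clavicle_z"],
            timestamps=t,
            values=clav + marker_noise,
            units=["m", "m", "m"],
            nominal_rate=cfg.grid_rate,
        ),
        "stim_envelope": TimedStream(
            name="stim_envelope",
            channel_labels=["LEFT", "RIGHT"],
            timestamps=t,
            values=env,
            units=["fraction", "fraction"],
            nominal_rate=cfg.grid_rate,
        ),
    }

    events = EventLog(
        [
            (0.0, "stand_start"),
            (cfg.stand_lead, "exercise_start"),
            (float(t[-1]), "sit_start"),
        ]
    )
    return SessionRecording(
        participant_id=p.participant_id,
        session_index=cfg.session_index if cfg.session_index is not None else 1,
        body_mass=p.body_mass,
        wheelchair_mass=p.wheelchair_mass,
        streams=streams,
        events=events,
        grid_rate=cfg.grid_rate,
    )


def _session_seeds(master_seed: int, n_sessions: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n_sessions)
    return [int(s % (2**31)) for s in state]


def iter_longitudinal(
    p: VirtualParticipant,
    n_sessions: int,
    cfg_template: SimConfig | None = None,
    master_seed: int = 0,
) -> Iterator[SessionRecording]:
    """Lazily yield one recording per session (memory-friendly for long series)."""
    if n_sessions < 1:
        raise ConfigurationError("n_sessions must be >= 1")
    if cfg_template is None:
        cfg_template = SimConfig(seed=0)
    for k, seed in enumerate(_session_seeds(master_seed, n_sessions), start=1):
        yield simulate_session(p, replace(cfg_template, seed=seed, session_index=k))


def simulate_longitudinal(
    p: VirtualParticipant,
    n_sessions: int,
    cfg_template: SimConfig | None = None,
    master_seed: int = 0,
) -> list[SessionRecording]:
    """One recording per session, with deterministic per-session seeds."""
    return list(iter_longitudinal(p, n_sessions, cfg_template, master_seed))


#: The three trial participants (sex M; masses from the study's intake table),
#: used as default fixtures by the CLI and the reproduction script.
def trial_participants() -> list[VirtualParticipant]:
    return [
        VirtualParticipant(participant_id="P1", body_mass=83.3, arm_strategy="push"),
        VirtualParticipant(participant_id="P3", body_mass=72.7, arm_strategy="push"),
        VirtualParticipant(participant_id="P5", body_mass=57.2, arm_strategy="pull"),
    ]
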