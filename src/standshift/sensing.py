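"""Sensor calibration and conversion models for the instrumented frame.

Arm-rail forces: each of the two rails reports 3 force DoF, each DoF being
the average of two co-planar load cells at opposite ends of the handle
(cancelling torque offsets). Each DoF carries a linear raw->newton
calibration fitted from a static weight sweep (0-58.5 kg in 4.5 kg steps).

Ground reaction: two 6-DoF force plates, each mapping six raw amplifier
outputs to a wrench (Fx, Fy, Fz, Mx, My, Mz) through a supplier 6x6
calibration matrix.

Raw sensor units are abstract counts/volts; only calibrated outputs carry
physical units. ``g = 9.81 m/s^2`` converts masses to forces throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, FitError

#: Standard acceleration due to gravity, m/s^2.
GRAVITY = 9.81

#: Static calibration sweep applied to every rail DoF, kg.
WEIGHT_SWEEP_KG = np.arange(0.0, 58.5 + 1e-9, 4.5)


def pair_average(cell_a, cell_b):
    """Mean of two co-planar load cells: one rail force DoF.

    Mounting the cells at opposite handle ends makes equal-and-opposite
    torque offsets cancel in the average.
    """
    a = np.asarray(cell_a, dtype=float)
    b = np.asarray(cell_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("load-cell readings must be finite")
    out = (a + b) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class LinearCalibration:
    """Linear raw->newton map for one force DoF: ``force = gain*raw + offset``."""

    gain: float
    offset: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gain) and self.gain != 0.0):
            raise FitError("calibration gain must be finite and nonzero")

    def apply(self, raw):
        return self.gain * np.asarray(raw, dtype=float) + self.offset

    def invert(self, force):
        """Raw reading that would produce ``force`` (simulation helper)."""
        return (np.asarray(force, dtype=float) - self.offset) / self.gain


@dataclass
class RailCalibration:
    """Per-DoF calibrations for one arm rail (keys: Fx, Fy, Fz)."""

    axes: dict[str, LinearCalibration]

    def apply(self, raw: np.ndarray, order=("Fx", "Fy", "Fz")) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        cols = [self.axes[k].apply(raw[..., i]) for i, k in enumerate(order)]
        return np.stack(cols, axis=-1)


def fit_linear_calibration(applied_masses_kg, readings) -> LinearCalibration:
    """Least-squares gain/offset mapping raw readings to force (mass * g).

    ``applied_masses_kg`` are the known static loads; ``readings`` the raw
    sensor outputs observed under each.
    """
    masses = np.asarray(applied_masses_kg, dtype=float)
    raw = np.asarray(readings, dtype=float)
    if masses.shape != raw.shape or masses.ndim != 1:
        raise FitError("masses and readings must be matching 1-D sequences")
    if np.unique(masses).size < 2:
        raise FitError("need at least 2 distinct applied masses")
    if np.ptp(raw) == 0.0:
        raise FitError("readings have zero variance; sensor not responding")
    force = masses * GRAVITY
    gain, offset = np.polyfit(raw, force, 1)
    resid = force - (gain * raw + offset)
    return LinearCalibration(
        gain=float(gain), offset=float(offset), residual_rms=float(np.sqrt(np.mean(resid**2)))
    )


@dataclass
class PlateCalibration:
    """6x6 raw->wrench calibration matrix for one force plate."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, 6):
            raise DataError("plate calibration matrix must be 6x6")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DataError("plate calibration matrix must be invertible")

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def apply_plate_matrix(raw, cal: PlateCalibration) -> np.ndarray:
    """Map raw plate outputs to a wrench (Fx, Fy, Fz, Mx, My, Mz).

    Accepts a single 6-vector or an (n, 6) array of samples.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] != 6:
        raise DataError(f"expected 6 raw plate channels, got {raw.shape[-1]}")
    return raw @ cal.matrix.T


def measure_participant_weight(combined_mass_kg: float, wheelchair_mass_kg: float) -> float:
    """Participant mass: combined (participant + wheelchair) minus wheelchair."""
    if wheelchair_mass_kg <= 0:
        raise DataError("wheelchair mass must be positive")
    body = combined_mass_kg - wheelchair_mass_kg
    if body <= 0:
        raise DataError(
            f"non-positive participant mass ({body:.3f} kg) from combined "
            f"{combined_mass_kg} kg and wheelchair {wheelchair_mass_kg} kg"
        )
    return body


# -- JSON persistence -------------------------------------------------------

def save_rail_calibration(cal: RailCalibration, path: str | Path) -> None:
    data = {
        k: {"gain": c.gain, "offset": c.offset, "residual_rms": c.residual_rms}
        for k, c in cal.axes.items()
    }
    Path(path).write_text(json.dumps(data, indent=1))


def load_rail_calibration(path: str | Path) -> RailCalibration:
    data = json.loads(Path(path).read_text())
    return RailCalibration({k: LinearCalibration(**v) for k, v in data.items()})


def save_plate_calibration(cal: PlateCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"matrix": cal.matrix.tolist()}, indent=1))


def load_plate_calibration(path: str | Path) -> PlateCalibration:
    return PlateCalibration(np.asarray(json.loads(Path(path).read_text())["matrix"]))
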