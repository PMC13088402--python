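"""Doppler-derived hemodynamics: flow volume and resistance index.

Units are kept consistent in the cgs convention common on ultrasound
consoles: vessel area in cm^2 and velocities in cm/s, so that

    FV [mL/min] = area [cm^2] * time-averaged velocity [cm/s] * 60 [s/min]

yields cm^3/min == mL/min directly.  Velocities reported in m/s can be
passed with ``velocity_unit="m/s"`` and are converted (x 100).

The time-averaged velocity is the per-beat velocity-time integral times
the beat rate: MTI [cm/beat] * HR [beats/min] / 60 [s/min] -> cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DopplerMeasurement",
    "HemodynamicResult",
    "time_averaged_velocity",
    "flow_volume",
    "resistance_index",
    "evaluate",
]


@dataclass(frozen=True)
class DopplerMeasurement:
    """One brachial-artery Doppler assessment.

    Parameters
    ----------
    vessel_area
        Lumen cross-sectional area, cm^2.
    mean_time_integral
        Velocity-time integral per beat, cm.
    heart_rate
        Beats per minute.
    peak_systolic_velocity, lowest_diastolic_velocity
        cm/s by default; pass ``velocity_unit="m/s"`` for m/s inputs.
    """

    vessel_area: float
    mean_time_integral: float
    heart_rate: float
    peak_systolic_velocity: float
    lowest_diastolic_velocity: float
    velocity_unit: str = "cm/s"

    def __post_init__(self) -> None:
        if self.velocity_unit not in ("cm/s", "m/s"):
            raise ValueError(f"velocity_unit must be 'cm/s' or 'm/s', got {self.velocity_unit!r}")
        if self.vessel_area <= 0:
            raise ValueError(f"vessel_area must be positive, got {self.vessel_area}")
        if self.heart_rate <= 0:
            raise ValueError(f"heart_rate must be positive, got {self.heart_rate}")
        if self.mean_time_integral < 0:
            raise ValueError("mean_time_integral must be nonnegative")
        if self.peak_systolic_velocity <= 0:
            raise ValueError(
                f"peak_systolic_velocity must be positive, got {self.peak_systolic_velocity}"
            )
        if not 0 <= self.lowest_diastolic_velocity <= self.peak_systolic_velocity:
            raise ValueError(
                "lowest_diastolic_velocity must lie in [0, peak_systolic_velocity]"
            )

    def _to_cm_s(self, v: float) -> float:
        return v * 100.0 if self.velocity_unit == "m/s" else v


@dataclass(frozen=True)
class HemodynamicResult:
    flow_volume: float  # mL/min
    resistance_index: float  # unitless, [0, 1]
    time_averaged_velocity: float  # cm/s

    def __post_init__(self) -> None:
        if self.flow_volume < 0:
            raise ValueError("flow_volume must be nonnegative")
        if not 0 <= self.resistance_index <= 1:
            raise ValueError("resistance_index must lie in [0, 1]")


def time_averaged_velocity(m: DopplerMeasurement) -> float:
    """Time-averaged velocity in cm/s: MTI per beat scaled by beats/second."""
    if m.heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    return m._to_cm_s(m.mean_time_integral) * m.heart_rate / 60.0


def flow_volume(m: DopplerMeasurement) -> float:
    """Brachial artery flow volume, mL/min."""
    if m.vessel_area <= 0:
        raise ValueError("vessel_area must be positive")
    return m.vessel_area * time_averaged_velocity(m) * 60.0


def resistance_index(m: DopplerMeasurement) -> float:
    """(peak systolic - lowest diastolic) / peak systolic velocity."""
    psv = m._to_cm_s(m.peak_systolic_velocity)
    edv = m._to_cm_s(m.lowest_diastolic_velocity)
    if psv <= 0:
        raise ValueError("peak_systolic_velocity must be positive")
    return (psv - edv) / psv


def evaluate(m: DopplerMeasurement) -> HemodynamicResult:
    """Compute FV, RI and TAV for one measurement."""
    return HemodynamicResult(
        flow_volume=flow_volume(m),
        resistance_index=resistance_index(m),
        time_averaged_velocity=time_averaged_velocity(m),
    )
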