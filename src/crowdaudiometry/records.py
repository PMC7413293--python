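"""Core domain types for crowdsourced audiometry records.

The record schema mirrors what a self-administered mobile hearing test
emits: per-ear, per-frequency hearing thresholds in dB HL on a 5 dB
grid, per-frequency measurement durations, device/model identifiers,
headphone connection status, optional user-entered age values, an
optional ambient-noise level (LAeq, dB(A)) and an ISO country code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

#: Test frequencies in Hz, in presentation order.
FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 6000, 8000)

#: The four frequencies entering the pure-tone average (PTA4).
PTA4_FREQUENCIES: tuple[int, ...] = (500, 1000, 2000, 4000)

EARS: tuple[str, str] = ("left", "right")

#: Step of the intensity grid, dB.
GRID_STEP: float = 5.0

#: Hardware limits of the stimulus level, dB HL.
LEVEL_FLOOR: float = -10.0
LEVEL_CEILING: float = 100.0


def on_grid(level: float, step: float = GRID_STEP) -> bool:
    """True if *level* lies on the 5 dB intensity grid."""
    return math.isclose(level / step, round(level / step), abs_tol=1e-9)


def quantize(level: float, step: float = GRID_STEP) -> float:
    """Round *level* to the nearest grid value (ties to even multiple)."""
    return round(level / step) * step


def clamp_level(level: float, lo: float = LEVEL_FLOOR, hi: float = LEVEL_CEILING) -> float:
    return min(max(level, lo), hi)


@dataclass
class Listener:
    """A virtual test subject.

    ``true_threshold`` maps ``(ear, frequency)`` to the genuine hearing
    threshold in dB HL. Behavioural parameters govern how the subject
    answers during the staircase: ``psychometric_slope`` is the width
    (dB) of the hear/not-hear transition, ``lapse_rate`` the per-trial
    probability of a random response, and ``confusion_prob`` the
    per-trial probability of responding to the contralateral masking
    noise instead of the test tone. ``speed_factor`` scales per-press
    response times.
    """

    age: int
    true_threshold: dict[tuple[str, int], float]
    psychometric_slope: float = 2.0
    lapse_rate: float = 0.0
    confusion_prob: float = 0.0
    speed_factor: float = 1.0

    def __post_init__(self) -> None:
        for ear in EARS:
            for f in FREQUENCIES:
                if (ear, f) not in self.true_threshold:
                    raise ValueError(f"missing true threshold for ({ear}, {f} Hz)")
        for key, thr in self.true_threshold.items():
            if not (LEVEL_FLOOR <= thr <= LEVEL_CEILING):
                raise ValueError(f"threshold {thr} dB HL out of range at {key}")
        for name in ("lapse_rate", "confusion_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.psychometric_slope < 0:
            raise ValueError("psychometric_slope must be >= 0")
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")

    def threshold(self, ear: str, frequency: int) -> float:
        return self.true_threshold[(ear, frequency)]

    def better_ear_pta4(self) -> float:
        """Better-ear pure-tone average over 0.5/1/2/4 kHz of the TRUE thresholds."""
        ptas = [
            sum(self.true_threshold[(ear, f)] for f in PTA4_FREQUENCIES) / len(PTA4_FREQUENCIES)
            for ear in EARS
        ]
        return min(ptas)


@dataclass
class DeviceModel:
    """A phone/headphone model with its acoustic deviation from nominal.

    ``true_offset[f]`` is the dB by which the bundled headphones'
    output at frequency ``f`` falls short of the nominal level, so an
    uncalibrated device with a positive offset inflates measured
    thresholds by that amount. ``calibration_coefficient`` is the
    biologically estimated correction (present only once calibrated).
    """

    model_id: str
    true_offset: dict[int, float]
    calibration_coefficient: Optional[dict[int, float]] = None
    headphones_bundled: bool = True

    def __post_init__(self) -> None:
        for f in FREQUENCIES:
            if f not in self.true_offset:
                raise ValueError(f"missing true_offset at {f} Hz")
            if not math.isfinite(self.true_offset[f]):
                raise ValueError(f"non-finite offset at {f} Hz")

    def stimulus_correction(self, frequency: int) -> float:
        """dB added to the nominal level to obtain the acoustic level at the ear."""
        coeff = 0.0
        if self.calibration_coefficient is not None:
            coeff = self.calibration_coefficient.get(frequency, 0.0)
        return coeff - self.true_offset[frequency]


@dataclass
class TestRecord:
    """One self-administered hearing test."""

    record_id: str
    device_id: str
    model_id: str
    timestamp: float
    headphone_connected: bool
    thresholds: dict[tuple[str, int], float]
    durations: dict[int, float]
    age_entries: list[int] = field(default_factory=list)
    laeq: Optional[float] = None
    country: str = "ZZ"

    def __post_init__(self) -> None:
        for (ear, f), thr in self.thresholds.items():
            if ear not in EARS or f not in FREQUENCIES:
                raise ValueError(f"unknown ear/frequency key ({ear}, {f})")
        for f, d in self.durations.items():
            if d <= 0:
                raise ValueError(f"non-positive duration {d} s at {f} Hz")

    def validate_grid(self) -> None:
        """Raise if any threshold is off the 5 dB grid.

        Raw app output is always on the grid; analytically adjusted
        records (e.g. after device-model centering) need not be, so
        this is enforced at I/O rather than construction.
        """
        for (ear, f), thr in self.thresholds.items():
            if not on_grid(thr):
                raise ValueError(
                    f"threshold {thr} dB HL at ({ear}, {f} Hz) is off the 5 dB grid"
                )

    @property
    def complete(self) -> bool:
        return all((ear, f) in self.thresholds for ear in EARS for f in FREQUENCIES)

    def mean_threshold(self) -> float:
        """Mean over all recorded per-ear, per-frequency thresholds."""
        if not self.thresholds:
            raise ValueError("record has no thresholds")
        return sum(self.thresholds.values()) / len(self.thresholds)
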