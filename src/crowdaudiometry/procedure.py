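"""Simulation of the self-administered staircase hearing test.

The app presents an amplitude-modulated pure tone whose intensity the
user adjusts in 5 dB steps with "I can hear" / "I can't hear" buttons,
confirming the quietest audible level with "Barely audible". When the
tone exceeds 40 dB HL a contralateral narrowband masker at 40 dB HL is
added, raised to 60 dB HL for tones above 60 dB HL. This module
simulates the user's button decisions; no audio is rendered.

Response model
--------------
The probability of "I can hear" is a logistic psychometric function of
``acoustic_level - effective_threshold`` with width
``psychometric_slope`` mixed with a lapse process (random response with
probability ``lapse_rate``). The effective threshold is the true
threshold elevated, for soft tones only, by an ambient-noise masking
floor that grows linearly with LAeq above a quiet reference. If the
masker is on, the subject responds "I can hear" with probability
``confusion_prob`` regardless of the tone (reacting to the masker
onset), which is the mechanism behind the 40-45 dB HL histogram spike
in high-threshold groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import (
    EARS,
    FREQUENCIES,
    GRID_STEP,
    LEVEL_CEILING,
    LEVEL_FLOOR,
    DeviceModel,
    Listener,
    TestRecord,
    on_grid,
)

#: Reference ambient level below which the room is treated as quiet, dB(A).
AMBIENT_REFERENCE_LAEQ: float = 35.0

#: Slope of the ambient masking floor in dB threshold per dB(A) LAeq above
#: the reference. Anchored so LAeq 60 dB(A) elevates a normal-hearing
#: (0 dB HL) threshold by 8 dB: 8 / (60 - 35) = 0.32.
AMBIENT_FLOOR_SLOPE: float = 8.0 / 25.0

#: Ambient noise cannot mask tones above this acoustic level, dB HL.
SOFT_TONE_CEILING: float = 40.0


@dataclass
class StaircaseConfig:
    """Parameters of the adaptive threshold search."""

    step: float = GRID_STEP
    start_level: float = 40.0
    level_floor: float = LEVEL_FLOOR
    level_ceiling: float = LEVEL_CEILING
    masking_on_threshold: float = 40.0
    masking_level_low: float = 40.0
    masking_boost_threshold: float = 60.0
    masking_level_high: float = 60.0
    frequency_set: tuple[int, ...] = FREQUENCIES
    #: lognormal (mu, sigma) of the per-button-press time in seconds;
    #: exp(0.7) ~ 2 s per press for an unhurried user
    trial_time_mu_log: float = 0.7
    trial_time_sigma_log: float = 0.35
    ambient_reference_laeq: float = AMBIENT_REFERENCE_LAEQ
    ambient_floor_slope: float = AMBIENT_FLOOR_SLOPE
    soft_tone_ceiling: float = SOFT_TONE_CEILING
    max_presses: int = 200

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.level_floor >= self.level_ceiling:
            raise ValueError("level_floor must be below level_ceiling")
        for name in ("masking_on_threshold", "masking_boost_threshold"):
            if not on_grid(getattr(self, name), self.step):
                raise ValueError(f"{name} must lie on the intensity grid")


@dataclass
class TrialOutcome:
    """Result of one staircase run: the confirmed threshold and timing."""

    measured_threshold: float
    duration: float
    trace: list[tuple[float, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def masking_level(tone_level: float, config: StaircaseConfig | None = None) -> Optional[float]:
    """Contralateral masker intensity for a given nominal tone level.

    Returns ``None`` when no masker is emitted (tone at or below
    40 dB HL), 40 dB HL for tones above 40 up to 60 dB HL, and
    60 dB HL for tones above 60 dB HL.
    """
    cfg = config or _DEFAULT_CONFIG
    if tone_level > cfg.masking_boost_threshold:
        return cfg.masking_level_high
    if tone_level > cfg.masking_on_threshold:
        return cfg.masking_level_low
    return None


def ambient_masked_floor(
    laeq: Optional[float],
    reference: float = AMBIENT_REFERENCE_LAEQ,
    slope: float = AMBIENT_FLOOR_SLOPE,
) -> float:
    """Threshold floor (dB HL) imposed by ambient noise at level *laeq*.

    Piecewise linear: zero at or below the quiet reference, rising by
    ``slope`` dB per dB(A) above it. ``None`` means an unmonitored but
    quiet room (floor at the grid minimum, i.e. no elevation).
    """
    if laeq is None or laeq <= reference:
        return LEVEL_FLOOR
    return slope * (laeq - reference)


def _hear_probability(
    listener: Listener,
    acoustic_level: float,
    effective_threshold: float,
) -> float:
    slope = listener.psychometric_slope
    if slope == 0.0:
        base = 1.0 if acoustic_level >= effective_threshold else 0.0
    else:
        base = 1.0 / (1.0 + math.exp(-(acoustic_level - effective_threshold) / slope))
    return listener.lapse_rate * 0.5 + (1.0 - listener.lapse_rate) * base


def listener_response(
    listener: Listener,
    ear: str,
    frequency: int,
    tone_level: float,
    masker: Optional[float],
    ambient_laeq: Optional[float],
    rng: np.random.Generator,
    config: StaircaseConfig | None = None,
) -> bool:
    """Simulate one button press: True = "I can hear".

    ``tone_level`` is the acoustic level reaching the ear (nominal plus
    any calibration error). The ambient floor applies only to soft
    tones — loud stimuli are not masked by room noise.
    """
    cfg = config or _DEFAULT_CONFIG
    if masker is not None and listener.confusion_prob > 0.0:
        if listener.confusion_prob >= 1.0 or rng.random() < listener.confusion_prob:
            return True
    eff = listener.threshold(ear, frequency)
    if tone_level <= cfg.soft_tone_ceiling:
        eff = max(
            eff,
            ambient_masked_floor(ambient_laeq, cfg.ambient_reference_laeq, cfg.ambient_floor_slope),
        )
    p = _hear_probability(listener, tone_level, eff)
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    return rng.random() < p


def run_staircase(
    listener: Listener,
    ear: str,
    frequency: int,
    ambient_laeq: Optional[float],
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
    stimulus_correction: float = 0.0,
) -> TrialOutcome:
    """Run the adaptive search for one ear and frequency.

    Descends in 5 dB steps from the start level while the subject
    hears, ascends while they do not, and confirms at the first
    ascending reversal (the lowest level answered "hear" with a
    "not hear" immediately below), or at the floor/ceiling.

    ``stimulus_correction`` is added to the nominal level to obtain the
    acoustic level at the ear (calibration coefficient minus the
    device's true offset); the recorded threshold stays on the nominal
    5 dB grid, which is how a miscalibrated device biases records.
    """
    cfg = config or _DEFAULT_CONFIG
    if frequency not in cfg.frequency_set:
        raise ValueError(f"frequency {frequency} Hz not in configured set")
    rng = np.random.default_rng() if rng is None else rng

    level = cfg.start_level
    trace: list[tuple[float, bool]] = []
    presses = 0
    descending: Optional[bool] = None
    confirmed: Optional[float] = None
    while presses < cfg.max_presses:
        acoustic = level + stimulus_correction
        masker = masking_level(level, cfg)
        heard = listener_response(
            listener, ear, frequency, acoustic, masker, ambient_laeq, rng, cfg
        )
        trace.append((level, heard))
        presses += 1
        if heard:
            if descending is False:
                # ascending reversal: lowest audible level bracketed from below
                confirmed = level
                break
            if level <= cfg.level_floor:
                confirmed = cfg.level_floor
                break
            descending = True
            level -= cfg.step
        else:
            if level >= cfg.level_ceiling:
                confirmed = cfg.level_ceiling
                break
            descending = False
            level += cfg.step
    if confirmed is None:
        raise RuntimeError(
            f"staircase did not terminate within {cfg.max_presses} presses "
            f"({ear}, {frequency} Hz)"
        )
    # one confirmation press on top of the adjustment presses
    presses += 1
    per_press = math.exp(rng.normal(cfg.trial_time_mu_log, cfg.trial_time_sigma_log))
    duration = presses * per_press * listener.speed_factor
    return TrialOutcome(measured_threshold=confirmed, duration=duration, trace=trace)


def run_full_test(
    listener: Listener,
    device: DeviceModel,
    ambient_laeq: Optional[float],
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | None = None,
    *,
    record_id: str = "r0",
    device_id: str = "d0",
    timestamp: float = 0.0,
    headphone_connected: bool = True,
    age_entries: Optional[list[int]] = None,
    laeq_recorded: bool = True,
    country: str = "ZZ",
) -> TestRecord:
    """Run the staircase for all configured frequencies and both ears.

    The per-frequency duration is the total time spent on that
    frequency across both ears. ``laeq_recorded=False`` emulates a user
    who declined microphone monitoring: the ambient level still shapes
    their responses but is absent from the record.
    """
    cfg = config or _DEFAULT_CONFIG
    rng = np.random.default_rng() if rng is None else rng
    thresholds: dict[tuple[str, int], float] = {}
    durations: dict[int, float] = {}
    for f in cfg.frequency_set:
        total = 0.0
        for ear in EARS:
            out = run_staircase(
                listener,
                ear,
                f,
                ambient_laeq,
                cfg,
                rng,
                stimulus_correction=device.stimulus_correction(f),
            )
            thresholds[(ear, f)] = out.measured_threshold
            total += out.duration
        durations[f] = total
    return TestRecord(
        record_id=record_id,
        device_id=device_id,
        model_id=device.model_id,
        timestamp=timestamp,
        headphone_connected=headphone_connected,
        thresholds=thresholds,
        durations=durations,
        age_entries=list(age_entries or []),
        laeq=ambient_laeq if laeq_recorded else None,
        country=country,
    )


_DEFAULT_CONFIG = StaircaseConfig()
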