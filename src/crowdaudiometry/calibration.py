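"""Biological calibration of device models and post-hoc model adjustment.

Biological calibration sets a model's reference output level from
measurements by subjects with normal hearing: the calibration
coefficient at each frequency is the mean deviation of the raw
measured thresholds from the expected normal-hearing threshold
(0 dB HL by the definition of the HL scale). At least 16 independent
measurements are required per model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import FREQUENCIES, TestRecord

MIN_CALIBRATION_MEASUREMENTS = 16


@dataclass
class CalibrationResult:
    model_id: str
    coefficient: dict[int, float]
    standard_error: dict[int, float]
    n_measurements: int

    def __post_init__(self) -> None:
        if self.n_measurements < MIN_CALIBRATION_MEASUREMENTS:
            raise ValueError(
                f"biological calibration requires at least "
                f"{MIN_CALIBRATION_MEASUREMENTS} measurements, got {self.n_measurements}"
            )
        if any(se < 0 for se in self.standard_error.values()):
            raise ValueError("standard errors must be non-negative")


def biological_calibrate(
    raw_thresholds: Sequence[dict[int, float]],
    expected_normal: Optional[dict[int, float]] = None,
    model_id: str = "model",
    trimmed: float = 0.0,
) -> CalibrationResult:
    """Estimate per-frequency calibration coefficients for one model.

    Parameters
    ----------
    raw_thresholds
        One complete frequency→dB map per normal-hearing subject.
    expected_normal
        Expected thresholds of normal-hearing subjects; defaults to
        0 dB HL at every frequency.
    trimmed
        Optional symmetric trimming fraction applied to each
        frequency's deviations before averaging (0 = plain mean).
    """
    expected = expected_normal or {f: 0.0 for f in FREQUENCIES}
    n = len(raw_thresholds)
    if n < MIN_CALIBRATION_MEASUREMENTS:
        raise ValueError(
            f"biological calibration requires at least "
            f"{MIN_CALIBRATION_MEASUREMENTS} measurements, got {n}"
        )
    if not (0.0 <= trimmed < 0.5):
        raise ValueError("trimmed fraction must be in [0, 0.5)")
    coefficient: dict[int, float] = {}
    standard_error: dict[int, float] = {}
    for f in FREQUENCIES:
        devs = []
        for i, subject in enumerate(raw_thresholds):
            if f not in subject:
                raise ValueError(f"subject {i} is missing frequency {f} Hz")
            devs.append(subject[f] - expected.get(f, 0.0))
        arr = np.sort(np.asarray(devs, dtype=float))
        if trimmed > 0.0:
            k = int(np.floor(trimmed * arr.size))
            if k > 0:
                arr = arr[k:-k]
        coefficient[f] = float(np.mean(arr))
        standard_error[f] = float(np.std(arr, ddof=1) / np.sqrt(arr.size))
    return CalibrationResult(
        model_id=model_id,
        coefficient=coefficient,
        standard_error=standard_error,
        n_measurements=n,
    )


def model_mean_thresholds(records: Sequence[TestRecord]) -> dict[str, float]:
    """Mean of per-record mean thresholds, by device model."""
    sums: dict[str, list[float]] = {}
    for rec in records:
        sums.setdefault(rec.model_id, []).append(rec.mean_threshold())
    return {m: float(np.mean(v)) for m, v in sums.items()}


def apply_model_adjustment(
    records: Sequence[TestRecord],
    model_means: Optional[dict[str, float]] = None,
) -> tuple[list[TestRecord], dict[str, float]]:
    """Remove between-model calibration differences from thresholds.

    Each model's centered mean threshold (model mean minus the grand
    mean over all adjustable records) is subtracted from its records'
    thresholds, so the grand mean is conserved. Models with fewer than
    two records are passed through unadjusted. Returns the adjusted
    records and the induced change in each country's mean threshold
    (after minus before, dB).
    """
    model_counts: dict[str, int] = {}
    for rec in records:
        model_counts[rec.model_id] = model_counts.get(rec.model_id, 0) + 1
    eligible = {m for m, c in model_counts.items() if c >= 2}
    adjustable = [r for r in records if r.model_id in eligible]
    if model_means is None:
        model_means = model_mean_thresholds(adjustable) if adjustable else {}
    else:
        missing = {r.model_id for r in adjustable} - set(model_means)
        if missing:
            raise ValueError(f"model_means missing models: {sorted(missing)}")
    if adjustable:
        grand = float(np.mean([model_means[r.model_id] for r in adjustable]))
    else:
        grand = 0.0

    before: dict[str, list[float]] = {}
    after: dict[str, list[float]] = {}
    adjusted: list[TestRecord] = []
    for rec in records:
        before.setdefault(rec.country, []).append(rec.mean_threshold())
        if rec.model_id in eligible:
            offset = model_means[rec.model_id] - grand
            new_thr = {k: v - offset for k, v in rec.thresholds.items()}
            rec = dataclasses.replace(rec, thresholds=new_thr)
        adjusted.append(rec)
        after.setdefault(rec.country, []).append(rec.mean_threshold())
    country_shift = {
        c: float(np.mean(after[c]) - np.mean(before[c])) for c in sorted(before)
    }
    return adjusted, country_shift
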