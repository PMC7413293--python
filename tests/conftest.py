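"""Shared fixtures and record-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from crowdaudiometry.cohort import CohortConfig, generate_cohort
from crowdaudiometry.records import EARS, FREQUENCIES, Listener, TestRecord


def flat_thresholds(value: float) -> dict[tuple[str, int], float]:
    return {(ear, f): float(value) for ear in EARS for f in FREQUENCIES}


def make_listener(
    threshold: float | dict[tuple[str, int], float] = 0.0,
    slope: float = 0.0,
    lapse: float = 0.0,
    confusion: float = 0.0,
    speed: float = 1.0,
    age: int = 40,
) -> Listener:
    thr = flat_thresholds(threshold) if not isinstance(threshold, dict) else dict(threshold)
    return Listener(
        age=age,
        true_threshold=thr,
        psychometric_slope=slope,
        lapse_rate=lapse,
        confusion_prob=confusion,
        speed_factor=speed,
    )


def make_record(
    record_id: str = "r1",
    device_id: str = "d1",
    threshold: float | dict[tuple[str, int], float] = 10.0,
    duration: float = 15.0,
    *,
    model_id: str = "m1",
    timestamp: float = 0.0,
    headphone_connected: bool = True,
    age_entries: list[int] | None = None,
    laeq: float | None = None,
    country: str = "PL",
) -> TestRecord:
    thr = flat_thresholds(threshold) if not isinstance(threshold, dict) else dict(threshold)
    freqs = sorted({f for (_, f) in thr})
    return TestRecord(
        record_id=record_id,
        device_id=device_id,
        model_id=model_id,
        timestamp=timestamp,
        headphone_connected=headphone_connected,
        thresholds=thr,
        durations={f: duration for f in freqs},
        age_entries=list(age_entries or []),
        laeq=laeq,
        country=country,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231118)


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size cohort under default (realistic) generator settings."""
    cfg = CohortConfig(
        n_devices=1500,
        tests_per_device_mean=1.0,
        country_prevalence_targets={"AA": 0.10, "BB": 0.30},
        rng_seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with repeat tests for I/O and QC integration tests."""
    cfg = CohortConfig(n_devices=60, rng_seed=7)
    return cfg, generate_cohort(cfg)
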