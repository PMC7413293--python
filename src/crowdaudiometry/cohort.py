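"""Synthetic cohorts of virtual listeners, devices, and test records.

Emulates the statistical structure of a crowdsourced smartphone
audiometry dataset: age-dependent bilateral thresholds, per-model
headphone calibration offsets, repeated tests per device, a rushed
(unreliable) test subpopulation with short durations, missing-at-random
age entries and ambient-noise monitoring, occasional
headphone-disconnected or incomplete tests, and country-specific
hearing-loss prevalence.

Age model
---------
No parametric threshold-vs-age law is implied by the data format, so
the generator uses a documented stand-in in the style of the ISO 7029
age correction: the mean threshold at frequency ``f`` rises
quadratically with age,

    mu(age, f) = base(f) + alpha(f) * (age - 18)**2,

with ``alpha`` growing toward high frequencies, plus a person-level
random effect shared across frequencies, independent per-ear effects,
and per-(ear, frequency) residual noise. Thresholds are clamped to
[-10, 100] dB HL and quantized to the 5 dB grid.

Country prevalence targets are enforced exactly in distribution: each
listener is drawn impaired with the country's target probability and
their thresholds shifted in 5 dB steps until the better-ear PTA4 falls
on the required side of 25 dB HL, so classifying listeners from their
true thresholds recovers the configured target up to binomial noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .procedure import StaircaseConfig, run_full_test
from .records import (
    EARS,
    FREQUENCIES,
    GRID_STEP,
    LEVEL_CEILING,
    LEVEL_FLOOR,
    PTA4_FREQUENCIES,
    DeviceModel,
    Listener,
    TestRecord,
    clamp_level,
    quantize,
)

#: ISO-7029-style aging coefficients, dB per (year - 18)^2.
DEFAULT_AGING_COEFF: dict[int, float] = {
    250: 0.0030,
    500: 0.0035,
    1000: 0.0040,
    2000: 0.0070,
    4000: 0.0160,
    6000: 0.0180,
    8000: 0.0220,
}

#: Decade weights of user-entered ages observed in crowdsourced
#: screening cohorts (youngest bin 18-19, oldest 90).
DEFAULT_AGE_BIN_WEIGHTS: tuple[tuple[int, int, float], ...] = (
    (18, 19, 0.103),
    (20, 29, 0.195),
    (30, 39, 0.221),
    (40, 49, 0.211),
    (50, 59, 0.150),
    (60, 69, 0.080),
    (70, 79, 0.031),
    (80, 89, 0.008),
    (90, 90, 0.002),
)


@dataclass
class AgeModel:
    """Quadratic-in-age mean threshold with Gaussian random effects."""

    base: dict[int, float] = field(default_factory=lambda: {f: 0.0 for f in FREQUENCIES})
    aging_coeff: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_AGING_COEFF))
    person_sd: float = 8.0
    ear_sd: float = 3.0
    residual_sd: float = 5.0
    age_ref: int = 18

    def mean(self, age: int, frequency: int) -> float:
        d = age - self.age_ref
        return self.base[frequency] + self.aging_coeff[frequency] * d * d

    def total_sd(self) -> float:
        return float(np.sqrt(self.person_sd**2 + self.ear_sd**2 + self.residual_sd**2))

    def expected_threshold(self, age: int, frequency: int) -> float:
        """Closed-form mean of the clamped Gaussian threshold.

        For X ~ N(mu, sd) clamped to [a, b]:
        E = a*Phi(alpha) + b*(1-Phi(beta)) + mu*(Phi(beta)-Phi(alpha))
            - sd*(phi(beta)-phi(alpha)).
        Quantization to the 5 dB grid is mean-preserving to well below
        the Monte-Carlo resolution this oracle is used at.
        """
        mu = self.mean(age, frequency)
        sd = self.total_sd()
        if sd == 0.0:
            return clamp_level(mu)
        a, b = LEVEL_FLOOR, LEVEL_CEILING
        alpha, beta = (a - mu) / sd, (b - mu) / sd
        return float(
            a * norm.cdf(alpha)
            + b * (1 - norm.cdf(beta))
            + mu * (norm.cdf(beta) - norm.cdf(alpha))
            - sd * (norm.pdf(beta) - norm.pdf(alpha))
        )


@dataclass
class CohortConfig:
    """Generator parameters; defaults emulate a crowdsourced screening cohort."""

    n_devices: int = 200
    tests_per_device_mean: float = 3.1  # 1 + Poisson(mean - 1)
    country_prevalence_targets: dict[str, float] = field(
        default_factory=lambda: {"PL": 0.16}
    )
    country_weights: Optional[dict[str, float]] = None
    age_model: AgeModel = field(default_factory=AgeModel)
    age_bin_weights: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_BIN_WEIGHTS
    age_present_prob: float = 0.07
    conflicting_age_prob: float = 0.02
    noise_monitoring_prob: float = 0.258
    ambient_laeq_mean: float = 45.0
    ambient_laeq_sd: float = 10.0
    ambient_laeq_range: tuple[float, float] = (25.0, 85.0)
    monitored_laeq_shift: float = -3.0  # users who consent to monitoring sit in quieter rooms
    fast_test_fraction: float = 0.6
    # rushed users mash through at ~0.3 s per press: the short-duration
    # component must sit well below unhurried tests for the
    # two-population structure to be identifiable
    fast_speed_log_mu: float = float(np.log(0.06))
    fast_speed_log_sigma: float = 0.25
    speed_log_sigma: float = 0.25
    incomplete_prob: float = 0.007
    disconnected_prob: float = 0.125
    n_models: Optional[int] = None  # default: ~1 model per 20 devices
    model_offset_sd: float = 4.0
    calibration_error_sd: float = 1.0
    psychometric_slope: float = 2.0
    lapse_rate: float = 0.02
    confusion_prob: float = 0.02
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "age_present_prob",
            "conflicting_age_prob",
            "noise_monitoring_prob",
            "fast_test_fraction",
            "incomplete_prob",
            "disconnected_prob",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_devices < 1:
            raise ValueError("n_devices must be >= 1")
        if self.tests_per_device_mean < 1:
            raise ValueError("tests_per_device_mean must be >= 1")
        for code, p in self.country_prevalence_targets.items():
            if not (len(code) == 2 and code.isalpha() and code.isupper()):
                raise ValueError(f"unknown country code {code!r}: expected ISO 3166-1 alpha-2")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence target for {code} must be in [0,1]")


@dataclass
class Cohort:
    """A generated dataset plus its ground truth (kept out of the records)."""

    records: list[TestRecord]
    listeners: dict[str, Listener]  # device_id -> owner
    models: dict[str, DeviceModel]
    device_model: dict[str, str]  # device_id -> model_id

    def true_prevalence(self, country: Optional[str] = None, countries: Optional[dict[str, str]] = None) -> float:
        """Oracle hearing-loss prevalence from TRUE listener thresholds."""
        device_country = countries or self.device_countries()
        flags = [
            listener.better_ear_pta4() > 25.0
            for dev, listener in self.listeners.items()
            if country is None or device_country.get(dev) == country
        ]
        if not flags:
            raise ValueError(f"no listeners for country {country!r}")
        return float(np.mean(flags))

    def device_countries(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rec in self.records:
            out.setdefault(rec.device_id, rec.country)
        return out


def _draw_age(config: CohortConfig, rng: np.random.Generator) -> int:
    bins = config.age_bin_weights
    w = np.array([b[2] for b in bins], dtype=float)
    w /= w.sum()
    i = rng.choice(len(bins), p=w)
    lo, hi, _ = bins[i]
    return int(rng.integers(lo, hi + 1))


def generate_listener(age: int, config: CohortConfig, rng: np.random.Generator) -> Listener:
    """Draw one virtual listener at the given age from the age model."""
    if not (18 <= age <= 90):
        raise ValueError(f"age {age} outside the supported 18-90 range")
    m = config.age_model
    person = rng.normal(0.0, m.person_sd)
    ear_eff = {ear: rng.normal(0.0, m.ear_sd) for ear in EARS}
    thresholds: dict[tuple[str, int], float] = {}
    for ear in EARS:
        for f in FREQUENCIES:
            x = m.mean(age, f) + person + ear_eff[ear] + rng.normal(0.0, m.residual_sd)
            thresholds[(ear, f)] = quantize(clamp_level(x))
    speed = float(np.exp(rng.normal(0.0, config.speed_log_sigma)))
    return Listener(
        age=age,
        true_threshold=thresholds,
        psychometric_slope=config.psychometric_slope,
        lapse_rate=config.lapse_rate,
        confusion_prob=config.confusion_prob,
        speed_factor=speed,
    )


def _enforce_class(listener: Listener, impaired: bool, rng: np.random.Generator) -> None:
    """Shift thresholds by 5 dB multiples until the better-ear PTA4 is
    strictly above 25 dB HL (impaired) or at/below it (not impaired)."""
    shifted = False
    for _ in range(1000):
        pta = listener.better_ear_pta4()
        if (impaired and pta > 25.0) or (not impaired and pta <= 25.0):
            if shifted:
                # spread enforced listeners geometrically away from the
                # cutoff so they do not pile up at exactly 25 dB HL
                extra = float(rng.geometric(0.35)) * GRID_STEP
                _shift_all(listener, extra if impaired else -extra)
            return
        _shift_all(listener, GRID_STEP if impaired else -GRID_STEP)
        shifted = True
    raise RuntimeError("could not enforce hearing-loss class")  # pragma: no cover


def _shift_all(listener: Listener, delta: float) -> None:
    for key, v in listener.true_threshold.items():
        listener.true_threshold[key] = clamp_level(v + delta)


def generate_devices(config: CohortConfig, rng: np.random.Generator) -> dict[str, DeviceModel]:
    """Draw device models with per-frequency offsets and calibration errors."""
    n_models = config.n_models or max(1, config.n_devices // 20)
    models: dict[str, DeviceModel] = {}
    for i in range(n_models):
        mid = f"m{i:04d}"
        offset = {f: float(rng.normal(0.0, config.model_offset_sd)) for f in FREQUENCIES}
        coeff = {
            f: offset[f] + float(rng.normal(0.0, config.calibration_error_sd))
            for f in FREQUENCIES
        }
        models[mid] = DeviceModel(
            model_id=mid,
            true_offset=offset,
            calibration_coefficient=coeff,
            headphones_bundled=True,
        )
    return models


def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Generate the full synthetic dataset. Deterministic under a fixed seed."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    models = generate_devices(config, rng)
    model_ids = sorted(models)
    countries = sorted(config.country_prevalence_targets)
    if config.country_weights is not None:
        cw = np.array([config.country_weights.get(c, 0.0) for c in countries], dtype=float)
        if cw.sum() <= 0:
            raise ValueError("country_weights assign no mass to configured countries")
        cw /= cw.sum()
    else:
        cw = np.full(len(countries), 1.0 / len(countries))

    records: list[TestRecord] = []
    listeners: dict[str, Listener] = {}
    device_model: dict[str, str] = {}
    rec_counter = 0
    for d in range(config.n_devices):
        device_id = f"d{d:06d}"
        model_id = model_ids[int(rng.integers(len(model_ids)))]
        device = models[model_id]
        device_model[device_id] = model_id
        country = countries[int(rng.choice(len(countries), p=cw))]
        target = config.country_prevalence_targets[country]
        age = _draw_age(config, rng)
        listener = generate_listener(age, config, rng)
        _enforce_class(listener, bool(rng.random() < target), rng)
        listeners[device_id] = listener

        n_tests = 1 + int(rng.poisson(config.tests_per_device_mean - 1.0))
        t0 = float(rng.uniform(0.0, 1e6))
        for k in range(n_tests):
            rec_counter += 1
            rushed = rng.random() < config.fast_test_fraction
            subject = listener
            if rushed:
                fast = float(
                    np.exp(rng.normal(config.fast_speed_log_mu, config.fast_speed_log_sigma))
                )
                subject = dataclasses.replace(
                    listener, true_threshold=listener.true_threshold, speed_factor=fast
                )
            monitored = rng.random() < config.noise_monitoring_prob
            laeq_mean = config.ambient_laeq_mean + (
                config.monitored_laeq_shift if monitored else 0.0
            )
            laeq = float(
                np.clip(
                    rng.normal(laeq_mean, config.ambient_laeq_sd),
                    *config.ambient_laeq_range,
                )
            )
            age_entries: list[int] = []
            if rng.random() < config.age_present_prob:
                age_entries = [listener.age]
                if rng.random() < config.conflicting_age_prob:
                    delta = int(rng.integers(1, 6))
                    age_entries.append(listener.age + delta)
            rec = run_full_test(
                subject,
                device,
                laeq,
                config.staircase,
                rng,
                record_id=f"r{rec_counter:08d}",
                device_id=device_id,
                timestamp=t0 + k * float(rng.uniform(60.0, 3600.0)),
                headphone_connected=not (rng.random() < config.disconnected_prob),
                age_entries=age_entries,
                laeq_recorded=monitored,
                country=country,
            )
            if rng.random() < config.incomplete_prob:
                _drop_entries(rec, rng)
            records.append(rec)
    return Cohort(records=records, listeners=listeners, models=models, device_model=device_model)


def _drop_entries(rec: TestRecord, rng: np.random.Generator) -> None:
    """Make a record incomplete by removing a random subset of measurements."""
    keys = [(ear, f) for ear in EARS for f in FREQUENCIES]
    n_drop = int(rng.integers(1, len(keys)))
    drop_idx = rng.choice(len(keys), size=n_drop, replace=False)
    for i in drop_idx:
        rec.thresholds.pop(keys[i], None)
    for f in FREQUENCIES:
        if all((ear, f) not in rec.thresholds for ear in EARS):
            rec.durations.pop(f, None)
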