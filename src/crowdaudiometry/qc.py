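"""Quality-control exclusion cascade for unsupervised self-tests.

Order of the cascade (each record attributed to its first failing
stage): completeness of all 7 frequencies in both ears, headphone
connection status, the per-frequency duration criterion, and finally
one-test-per-device selection. The duration threshold is estimated by
fitting a lognormal to the short (rushed, unreliable) duration
component and taking its quantile at cumulative probability 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .records import TestRecord


@dataclass
class ExclusionFlow:
    """Counts of records removed at each cascade stage."""

    n_total: int
    n_incomplete: int
    n_no_headphones: int
    n_too_fast: int
    n_device_duplicates: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (
            self.n_incomplete,
            self.n_no_headphones,
            self.n_too_fast,
            self.n_device_duplicates,
            self.n_retained,
        )
        if any(c < 0 for c in counts):
            raise ValueError("exclusion counts must be non-negative")
        if sum(counts) != self.n_total:
            raise ValueError("exclusion counts do not sum to n_total")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_incomplete": self.n_incomplete,
            "n_no_headphones": self.n_no_headphones,
            "n_too_fast": self.n_too_fast,
            "n_device_duplicates": self.n_device_duplicates,
            "n_retained": self.n_retained,
        }


@dataclass
class DurationModel:
    """Lognormal model of the (short) per-frequency duration component."""

    mu_log: float
    sigma_log: float
    quantile_level: float = 0.99

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if not (0.0 < self.quantile_level < 1.0):
            raise ValueError("quantile_level must be in (0, 1)")

    @property
    def threshold_seconds(self) -> float:
        return float(np.exp(self.mu_log + self.sigma_log * norm.ppf(self.quantile_level)))


def is_complete(record: TestRecord) -> bool:
    """True iff thresholds are present for all 7 frequencies in both ears."""
    return record.complete


def consolidate_age(age_entries: Sequence[int]) -> Optional[int]:
    """The unique entered age, or None if no entry or conflicting entries."""
    unique = set(age_entries)
    if len(unique) == 1:
        return int(next(iter(unique)))
    return None


def fit_duration_model(
    durations: Sequence[float],
    quantile_level: float = 0.99,
    mixture: bool = True,
) -> DurationModel:
    """Fit the duration model used for the time criterion.

    With ``mixture=True`` (default) a two-component Gaussian mixture is
    fitted to log durations and the component with the smaller mean —
    the rushed, unreliable subpopulation — is returned. With
    ``mixture=False`` a single lognormal is fitted by maximum
    likelihood to all durations.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 30:
        raise ValueError(f"need at least 30 durations, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    logs = np.log(d)
    if np.ptp(logs) == 0:
        raise ValueError("degenerate durations: zero variance")
    if not mixture:
        mu = float(np.mean(logs))
        sigma = float(np.std(logs))  # MLE (ddof=0)
        return DurationModel(mu_log=mu, sigma_log=sigma, quantile_level=quantile_level)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=0)
    gm.fit(logs.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    short = int(np.argmin(means))
    if sds[short] <= 0:
        raise ValueError("degenerate short-duration component")
    return DurationModel(
        mu_log=float(means[short]), sigma_log=float(sds[short]), quantile_level=quantile_level
    )


def estimate_duration_threshold(
    durations: Sequence[float],
    quantile_level: float = 0.99,
    mixture: bool = True,
) -> float:
    """Duration threshold in seconds: the fitted (short-component)
    lognormal's quantile at ``quantile_level``."""
    return fit_duration_model(durations, quantile_level, mixture).threshold_seconds


def _min_duration(record: TestRecord) -> float:
    if not record.durations:
        return float("inf")
    return min(record.durations.values())


def apply_exclusions(
    records: Sequence[TestRecord],
    duration_threshold: float,
) -> tuple[list[TestRecord], ExclusionFlow]:
    """Run the exclusion cascade and return retained records plus counts.

    Deduplication keeps, per device, the latest record that has a
    consolidated (non-conflicting) age if any such record survives the
    earlier stages, otherwise the latest record overall; timestamp ties
    break by record_id.
    """
    if duration_threshold <= 0:
        raise ValueError("duration_threshold must be positive")
    n_total = len(records)
    n_incomplete = n_no_headphones = n_too_fast = 0
    survivors: list[TestRecord] = []
    for rec in records:
        if not is_complete(rec):
            n_incomplete += 1
        elif not rec.headphone_connected:
            n_no_headphones += 1
        elif _min_duration(rec) < duration_threshold:
            n_too_fast += 1
        else:
            survivors.append(rec)

    by_device: dict[str, list[TestRecord]] = {}
    for rec in survivors:
        by_device.setdefault(rec.device_id, []).append(rec)
    retained: list[TestRecord] = []
    for device_id in sorted(by_device):
        group = by_device[device_id]
        with_age = [r for r in group if consolidate_age(r.age_entries) is not None]
        pool = with_age if with_age else group
        retained.append(max(pool, key=lambda r: (r.timestamp, r.record_id)))
    n_duplicates = len(survivors) - len(retained)
    flow = ExclusionFlow(
        n_total=n_total,
        n_incomplete=n_incomplete,
        n_no_headphones=n_no_headphones,
        n_too_fast=n_too_fast,
        n_device_duplicates=n_duplicates,
        n_retained=len(retained),
    )
    return retained, flow
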