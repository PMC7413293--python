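"""Hearing-loss epidemiology on filtered test records.

Covers classification (better-ear four-frequency pure-tone average
above 25 dB HL), country-stratified prevalence with percentile
bootstrap confidence intervals and a minimum-sample-size gate, the
power calculation behind that gate, age-decade median threshold
curves, Kolmogorov-Smirnov subgroup comparison, the ambient-noise
effect and its component combination, country-difference arithmetic,
and the masking-confusion bias score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .records import EARS, FREQUENCIES, PTA4_FREQUENCIES, TestRecord

#: Hearing-loss criterion: better-ear PTA4 strictly above this, dB HL.
HEARING_LOSS_CUTOFF: float = 25.0

#: Reference quiet ambient level for the noise adjustment, dB(A).
REFERENCE_LAEQ: float = 35.0


@dataclass
class PrevalenceEstimate:
    country: str
    n: int
    prevalence: float  # percent
    ci_low: float
    ci_high: float
    included: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.prevalence <= self.ci_high <= 100.0):
            raise ValueError(
                f"invalid prevalence CI for {self.country}: "
                f"({self.ci_low}, {self.prevalence}, {self.ci_high})"
            )


@dataclass
class NoiseEffect:
    per_bin_delta: dict[float, float]
    adjustment_mean: float
    adjustment_sd: float
    group_difference_mean: float
    group_difference_sd: float
    overall_mean: float = field(init=False)
    overall_sd: float = field(init=False)
    prevalence_reduction: float = 0.0

    def __post_init__(self) -> None:
        self.overall_mean = self.adjustment_mean + self.group_difference_mean
        self.overall_sd = math.hypot(self.adjustment_sd, self.group_difference_sd)


@dataclass
class PowerSpec:
    """Inputs of the minimum-sample-size calculation."""

    sd: float = 17.0
    effect: float = 5.0
    alpha: float = 0.05
    power: float = 0.8

    @property
    def min_n(self) -> int:
        return min_sample_size(self.sd, self.effect, self.alpha, self.power)


def pta4(record: TestRecord, ear: str) -> float:
    """Pure-tone average over 0.5, 1, 2 and 4 kHz for one ear, dB HL."""
    vals = []
    for f in PTA4_FREQUENCIES:
        if (ear, f) not in record.thresholds:
            raise ValueError(f"record {record.record_id}: missing {f} Hz for {ear} ear")
        vals.append(record.thresholds[(ear, f)])
    return float(np.mean(vals))


def classify_hearing_loss(record: TestRecord, cutoff: float = HEARING_LOSS_CUTOFF) -> bool:
    """True iff the better-ear PTA4 is strictly above the cutoff."""
    return min(pta4(record, ear) for ear in EARS) > cutoff


def min_sample_size(sd: float, effect: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Minimum per-country n to resolve *effect* dB, one-sample normal
    approximation: floor(((z_{1-alpha/2} + z_power) * sd / effect)^2),
    at least 1."""
    if sd <= 0 or effect <= 0:
        raise ValueError("sd and effect must be positive")
    if not (0.0 < alpha < 1.0) or not (0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return max(1, int(math.floor((z * sd / effect) ** 2)))


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval of *statistic* over *values*."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    if n_boot < 200:
        raise ValueError(f"n_boot must be at least 200, got {n_boot}")
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if x.size == 1 or np.ptp(x) == 0.0:
        v = float(statistic(x))
        return v, v
    reps = np.empty(n_boot)
    # chunk the resample matrix to bound memory on large inputs
    chunk = max(1, min(n_boot, int(2e7 // x.size)))
    fast = statistic is np.mean or statistic is np.median
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, x.size, size=(m, x.size))
        if fast:
            reps[done : done + m] = statistic(x[idx], axis=1)
        else:
            for j in range(m):
                reps[done + j] = statistic(x[idx[j]])
        done += m
    lo_q = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(reps, [lo_q, 1.0 - lo_q])
    return float(lo), float(hi)


def country_prevalence(
    records: Sequence[TestRecord],
    min_n: int = 90,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    rng_seed: int | None = 0,
) -> tuple[list[PrevalenceEstimate], PrevalenceEstimate]:
    """Per-country and pooled hearing-loss prevalence with bootstrap CIs."""
    if not records:
        raise ValueError("no records to analyze")
    rng = np.random.default_rng(rng_seed)
    by_country: dict[str, list[float]] = {}
    pooled: list[float] = []
    for rec in records:
        flag = 1.0 if classify_hearing_loss(rec) else 0.0
        by_country.setdefault(rec.country, []).append(flag)
        pooled.append(flag)

    def _estimate(country: str, flags: list[float], included_gate: bool) -> PrevalenceEstimate:
        arr = np.asarray(flags)
        prev = float(arr.mean()) * 100.0
        lo, hi = bootstrap_ci(arr, np.mean, n_boot=n_boot, ci_level=ci_level, rng=rng)
        return PrevalenceEstimate(
            country=country,
            n=arr.size,
            prevalence=prev,
            ci_low=min(lo * 100.0, prev),
            ci_high=max(hi * 100.0, prev),
            included=(arr.size >= min_n) if included_gate else True,
        )

    estimates = [_estimate(c, by_country[c], True) for c in sorted(by_country)]
    global_est = _estimate("GLOBAL", pooled, False)
    return estimates, global_est


def ks_equivalence(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of threshold
    distributions: (D, asymptotic p). Non-rejection at the chosen level
    is read as equivalence of the subgroups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


AGE_DECADES: tuple[tuple[int, int], ...] = tuple((d, d + 9) for d in range(20, 90, 10))


def age_median_curves(
    records: Sequence[TestRecord],
    n_boot: int = 2000,
    ci_level: float = 0.95,
    rng_seed: int | None = 0,
    better_ear_only: bool = False,
) -> dict[tuple[str, int], tuple[float, float, float]]:
    """Median threshold (and bootstrap CI) per age decade and frequency.

    Uses records with a consolidated age in 20-89 (18, 19 and 90 are
    dropped to keep equal decade ranges). Both ears are pooled per
    frequency by default.
    """
    from .qc import consolidate_age

    rng = np.random.default_rng(rng_seed)
    groups: dict[tuple[str, int], list[float]] = {}
    for rec in records:
        age = consolidate_age(rec.age_entries)
        if age is None or not (20 <= age <= 89):
            continue
        lo = (age // 10) * 10
        label = f"{lo}-{lo + 9}"
        for f in FREQUENCIES:
            if better_ear_only:
                if all((ear, f) in rec.thresholds for ear in EARS):
                    groups.setdefault((label, f), []).append(
                        min(rec.thresholds[(ear, f)] for ear in EARS)
                    )
            else:
                for ear in EARS:
                    if (ear, f) in rec.thresholds:
                        groups.setdefault((label, f), []).append(rec.thresholds[(ear, f)])
    out: dict[tuple[str, int], tuple[float, float, float]] = {}
    for key in sorted(groups):
        vals = np.asarray(groups[key])
        med = float(np.median(vals))
        lo_ci, hi_ci = bootstrap_ci(vals, np.median, n_boot=n_boot, ci_level=ci_level, rng=rng)
        out[key] = (med, lo_ci, hi_ci)
    return out


def combine_noise_components(
    adjustment_mean: float,
    adjustment_sd: float,
    group_difference_mean: float,
    group_difference_sd: float,
) -> tuple[float, float]:
    """Combine the within-monitored adjustment and the monitored-vs-
    unmonitored group difference: means add, uncertainties add in
    quadrature."""
    return (
        adjustment_mean + group_difference_mean,
        math.hypot(adjustment_sd, group_difference_sd),
    )


def _laeq_bin(laeq: float, reference: float, width: float) -> float:
    """Lower edge of the LAeq bin; the reference bin is labelled by the
    reference level itself and collects everything at or below it."""
    if laeq <= reference:
        return reference
    k = math.ceil((laeq - reference) / width)
    return reference + (k - 1) * width


def noise_effect(
    records: Sequence[TestRecord],
    reference_laeq: float = REFERENCE_LAEQ,
    bin_width: float = 5.0,
    n_boot: int = 200,
    rng_seed: int | None = 0,
) -> NoiseEffect:
    """Estimate the ambient-noise effect on measured thresholds.

    Monitored records are binned by LAeq; the mean-threshold difference
    of each bin versus the quiet reference bin gives the per-bin
    elevation. The adjustment is the cohort-weighted mean decrease
    obtained by shifting every monitored record to the reference, with
    a bootstrap standard error. The monitored-minus-unmonitored group
    difference (reported as the positive "lower by" magnitude) is added
    to give the overall effect; the prevalence_reduction is the change
    in global prevalence (percentage points) after subtracting the
    overall effect from all thresholds.
    """
    monitored = [r for r in records if r.laeq is not None]
    unmonitored = [r for r in records if r.laeq is None]
    if not monitored:
        raise ValueError("no ambient-noise-monitored records")
    rng = np.random.default_rng(rng_seed)

    laeqs = np.array([r.laeq for r in monitored], dtype=float)
    means = np.array([r.mean_threshold() for r in monitored], dtype=float)
    bins = np.array([_laeq_bin(l, reference_laeq, bin_width) for l in laeqs])
    bin_labels = np.unique(bins)
    if bin_labels.size < 2:
        if np.all(bins == reference_laeq):
            # everything already in the quiet reference bin: nothing to adjust
            per_bin = {float(reference_laeq): 0.0}
            adj_mean, adj_sd = 0.0, 0.0
        else:
            raise ValueError("reference LAeq bin is empty; cannot form differences")
    else:
        if reference_laeq not in bin_labels:
            raise ValueError("reference LAeq bin is empty; cannot form differences")

        def _per_record_delta(b: np.ndarray, m: np.ndarray) -> Optional[np.ndarray]:
            ref_mask = b == reference_laeq
            if not ref_mask.any():
                return None
            ref_mean = m[ref_mask].mean()
            deltas = np.zeros_like(m)
            for lab in np.unique(b):
                mask = b == lab
                deltas[mask] = m[mask].mean() - ref_mean
            return deltas

        deltas = _per_record_delta(bins, means)
        assert deltas is not None
        per_bin = {
            float(lab): float(means[bins == lab].mean() - means[bins == reference_laeq].mean())
            for lab in bin_labels
        }
        adj_mean = float(deltas.mean())
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(monitored), size=len(monitored))
            d = _per_record_delta(bins[idx], means[idx])
            if d is not None:
                reps.append(d.mean())
        adj_sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0

    if unmonitored:
        um = np.array([r.mean_threshold() for r in unmonitored])
        diff = float(um.mean() - means.mean())  # positive when monitored lower
        diff_sd = float(
            math.sqrt(um.var(ddof=1) / um.size + means.var(ddof=1) / means.size)
            if um.size > 1 and means.size > 1
            else 0.0
        )
    else:
        diff, diff_sd = 0.0, 0.0

    effect = NoiseEffect(
        per_bin_delta=per_bin,
        adjustment_mean=adj_mean,
        adjustment_sd=adj_sd,
        group_difference_mean=diff,
        group_difference_sd=diff_sd,
    )

    classifiable = [r for r in records if r.complete]
    if classifiable:
        before = np.mean([classify_hearing_loss(r) for r in classifiable]) * 100.0
        shift = effect.overall_mean
        after_flags = []
        for r in classifiable:
            shifted = {k: v - shift for k, v in r.thresholds.items()}
            ptas = [
                np.mean([shifted[(ear, f)] for f in PTA4_FREQUENCIES]) for ear in EARS
            ]
            after_flags.append(min(ptas) > HEARING_LOSS_CUTOFF)
        after = np.mean(after_flags) * 100.0
        effect.prevalence_reduction = float(before - after)
    return effect


def country_difference(
    p_high: float, p_low: float, conventional: bool = False
) -> tuple[float, float]:
    """Relative and absolute difference between two prevalences (percent).

    The default relative measure is (p_high - p_low) / p_high * 100;
    ``conventional=True`` uses the lower prevalence as the base
    instead.
    """
    if p_high <= 0:
        raise ValueError("p_high must be positive")
    if not (0 < p_low <= p_high <= 100):
        raise ValueError("require 0 < p_low <= p_high <= 100")
    absolute = p_high - p_low
    base = p_low if conventional else p_high
    return absolute / base * 100.0, absolute


def masking_bias_score(
    thresholds: Sequence[float],
    spike_levels: tuple[float, float] = (40.0, 45.0),
    grid_step: float = 5.0,
) -> tuple[float, Optional[dict[str, float]]]:
    """Excess probability mass at the masker-onset levels (40/45 dB HL).

    Fits a lognormal to the threshold histogram excluding the spike
    bins (values shifted by +15 dB so the -10 dB HL floor maps to
    positive support) and returns the observed-minus-predicted mass in
    those bins, clamped at zero, together with the fitted parameters.
    A large score indicates listeners responding to the contralateral
    masker instead of the tone.
    """
    x = np.asarray(thresholds, dtype=float)
    if x.size < 100:
        raise ValueError(f"need at least 100 thresholds, got {x.size}")
    half = grid_step / 2.0
    spike_mask = np.zeros(x.size, dtype=bool)
    for lev in spike_levels:
        spike_mask |= np.abs(x - lev) < half
    m_obs = float(spike_mask.mean())
    rest = x[~spike_mask]
    # map the -10 dB HL floor onto positive support for the lognormal
    shift = max(15.0, float(-x.min()) + half)
    if rest.size < 10 or np.ptp(rest) == 0.0:
        # degenerate: essentially everything sits in the spike bins
        return m_obs, None

    # binned lognormal MLE, truncated to the non-spike bins: the
    # likelihood of each grid bin is renormalized by 1 - P(spike bins)
    # so cutting the spike bins out does not bias the fit
    bins, counts = np.unique(rest, return_counts=True)

    def _p_bins(mu: float, sigma: float, centers: np.ndarray) -> np.ndarray:
        z_hi = (np.log(centers + half + shift) - mu) / sigma
        z_lo = (np.log(centers - half + shift) - mu) / sigma
        return stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)

    spikes = np.asarray(spike_levels, dtype=float)

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        p_rest = _p_bins(mu, sigma, bins)
        p_spike = _p_bins(mu, sigma, spikes).sum()
        if np.any(p_rest <= 0) or p_spike >= 1.0:
            return 1e12
        return float(-(counts * np.log(p_rest)).sum() + counts.sum() * math.log1p(-p_spike))

    logs = np.log(rest + shift)
    res = optimize.minimize(
        nll,
        x0=np.array([logs.mean(), math.log(max(logs.std(), 1e-3))]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    mu_hat, sigma_hat = float(res.x[0]), float(math.exp(res.x[1]))
    p_spike = float(_p_bins(mu_hat, sigma_hat, spikes).sum())
    params = {"mu_log": mu_hat, "sigma_log": sigma_hat, "shift": shift}
    if p_spike >= 1.0:
        return 0.0, params
    predicted = p_spike * (1.0 - m_obs) / (1.0 - p_spike)
    excess = max(0.0, m_obs - predicted)
    return excess, params


def country_heterogeneity(records: Sequence[TestRecord]) -> tuple[float, float]:
    """Chi-square test of country x hearing-loss association: (stat, p)."""
    table: dict[str, list[int]] = {}
    for rec in records:
        row = table.setdefault(rec.country, [0, 0])
        row[classify_hearing_loss(rec)] += 1
    counts = np.array([v for v in table.values()])
    counts = counts[(counts.sum(axis=1) > 0)]
    if counts.shape[0] < 2 or np.any(counts.sum(axis=0) == 0):
        raise ValueError("need at least two countries and both outcome classes")
    res = stats.chi2_contingency(counts)
    return float(res.statistic), float(res.pvalue)
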