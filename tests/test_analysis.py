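"""Classification, prevalence, bootstrap, noise effect, and bias scores."""

from __future__ import annotations

import numpy as np
import pytest

from crowdaudiometry.analysis import (
    NoiseEffect,
    PowerSpec,
    bootstrap_ci,
    classify_hearing_loss,
    combine_noise_components,
    country_difference,
    country_heterogeneity,
    country_prevalence,
    age_median_curves,
    ks_equivalence,
    masking_bias_score,
    min_sample_size,
    noise_effect,
    pta4,
)
from crowdaudiometry.records import EARS, PTA4_FREQUENCIES

from conftest import flat_thresholds, make_record


def record_with_ptas(left: float, right: float, record_id="r1", device_id="d1", **kw):
    thr = flat_thresholds(0.0)
    for f in PTA4_FREQUENCIES:
        thr[("left", f)] = left
        thr[("right", f)] = right
    return make_record(record_id, device_id, thr, **kw)


class TestPTA4:
    def test_arithmetic_mean(self):
        thr = flat_thresholds(0.0)
        for f, v in zip(PTA4_FREQUENCIES, (20.0, 20.0, 30.0, 30.0)):
            thr[("left", f)] = v
        assert pta4(make_record(threshold=thr), "left") == 25.0

    @pytest.mark.parametrize("vals,expected", [((0, 0, 0, 0), 0.0), ((10, 20, 30, 40), 25.0)])
    def test_examples(self, vals, expected):
        thr = flat_thresholds(0.0)
        for f, v in zip(PTA4_FREQUENCIES, vals):
            thr[("right", f)] = float(v)
        assert pta4(make_record(threshold=thr), "right") == expected

    def test_missing_frequency_errors(self):
        rec = make_record()
        del rec.thresholds[("left", 2000)]
        with pytest.raises(ValueError):
            pta4(rec, "left")


class TestClassification:
    def test_better_ear_rule(self):
        assert not classify_hearing_loss(record_with_ptas(20.0, 40.0))
        assert not classify_hearing_loss(record_with_ptas(40.0, 20.0))

    def test_strictly_above_25(self):
        assert not classify_hearing_loss(record_with_ptas(25.0, 25.0))
        assert classify_hearing_loss(record_with_ptas(30.0, 30.0))

    @pytest.mark.parametrize("left,right", [(20, 40), (30, 50), (25, 30), (60, 60)])
    def test_ear_swap_invariance(self, left, right):
        assert classify_hearing_loss(
            record_with_ptas(float(left), float(right))
        ) == classify_hearing_loss(record_with_ptas(float(right), float(left)))


class TestMinSampleSize:
    def test_preliminary_power_calculation(self):
        # sigma 17 dB, effect 5 dB, alpha .05, power .8 -> 90 tests
        assert min_sample_size(17, 5, 0.05, 0.8) == 90
        assert PowerSpec().min_n == 90

    def test_unit_effect_ratio(self):
        assert min_sample_size(17, 17, 0.05, 0.8) == 7

    def test_huge_effect_clamped_to_one(self):
        assert min_sample_size(17, 1000, 0.05, 0.8) == 1

    def test_invalid_inputs(self):
        for args in [(0, 5, 0.05, 0.8), (17, 0, 0.05, 0.8), (17, 5, 1.5, 0.8), (17, 5, 0.05, 0.0)]:
            with pytest.raises(ValueError):
                min_sample_size(*args)

    def test_monotone_in_sd_and_effect(self):
        for sd_lo, sd_hi in [(5, 10), (10, 17), (17, 30)]:
            assert min_sample_size(sd_lo, 5) <= min_sample_size(sd_hi, 5)
        for e_lo, e_hi in [(2, 5), (5, 10), (10, 20)]:
            assert min_sample_size(17, e_lo) >= min_sample_size(17, e_hi)


class TestBootstrap:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bootstrap_ci([4.0] * 50, np.mean, rng=0)
        assert (lo, hi) == (4.0, 4.0)

    def test_n_boot_floor(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0], np.mean, n_boot=199)

    def test_seeded_reproducible(self):
        x = np.arange(30.0)
        assert bootstrap_ci(x, np.mean, rng=5) == bootstrap_ci(x, np.mean, rng=5)

    def test_median_interval_coverage(self):
        """Percentile bootstrap for the median covers the true value at
        roughly the nominal 95% rate under a normal population."""
        rng = np.random.default_rng(101)
        cover = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=1001)
            lo, hi = bootstrap_ci(x, np.median, n_boot=400, rng=rng)
            cover += lo <= 0.0 <= hi
        assert 0.90 <= cover / reps <= 1.0


class TestCountryPrevalence:
    def test_fraction_and_gate(self):
        records = [
            record_with_ptas(40.0, 40.0, f"r{i}", f"d{i}", country="AA") for i in range(15)
        ] + [
            record_with_ptas(10.0, 10.0, f"s{i}", f"e{i}", country="AA") for i in range(85)
        ] + [
            record_with_ptas(10.0, 10.0, f"t{i}", f"f{i}", country="BB") for i in range(89)
        ]
        estimates, global_est = country_prevalence(records, min_n=90, n_boot=500, rng_seed=0)
        by = {e.country: e for e in estimates}
        assert by["AA"].prevalence == pytest.approx(15.0)
        assert by["AA"].included
        assert not by["BB"].included
        assert global_est.n == len(records)

    def test_all_loss_country_degenerate_ci(self):
        records = [record_with_ptas(40.0, 40.0, f"r{i}", f"d{i}") for i in range(10)]
        estimates, _ = country_prevalence(records, n_boot=500)
        assert estimates[0].prevalence == 100.0
        assert (estimates[0].ci_low, estimates[0].ci_high) == (100.0, 100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            country_prevalence([])


class TestKS:
    def test_identical_samples(self):
        d, _ = ks_equivalence([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = ks_equivalence([0.0] * 4, [10.0] * 4)
        assert d == 1.0
        assert p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ks_equivalence([], [1.0])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(44)
        ps = []
        for _ in range(300):
            a, b = rng.normal(size=(2, 500))
            ps.append(ks_equivalence(a, b)[1])
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() < 0.12


class TestAgeCurves:
    def test_median_and_exclusions(self):
        records = []
        for i, (age, thr) in enumerate([(25, 10.0), (25, 20.0), (25, 30.0), (19, 90.0), (90, 90.0)]):
            records.append(
                make_record(f"r{i}", f"d{i}", thr, age_entries=[age])
            )
        records.append(make_record("r9", "d9", 90.0))  # no age: excluded
        curves = age_median_curves(records, n_boot=300)
        groups = {g for g, _ in curves}
        assert groups == {"20-29"}
        med, lo, hi = curves[("20-29", 1000)]
        assert med == 20.0

    def test_constant_group_degenerate_ci(self):
        records = [
            make_record(f"r{i}", f"d{i}", 0.0, age_entries=[42]) for i in range(5)
        ]
        curves = age_median_curves(records, n_boot=300)
        assert curves[("40-49", 500)] == (0.0, 0.0, 0.0)


class TestNoiseEffect:
    def test_component_combination(self):
        mean, sd = combine_noise_components(2.53, 0.74, 1.25, 0.12)
        assert mean == pytest.approx(3.78)
        assert sd == pytest.approx(0.75, abs=0.005)

    def test_invariant_holds_by_construction(self):
        eff = NoiseEffect({}, 2.53, 0.74, 1.25, 0.12)
        assert eff.overall_mean == pytest.approx(eff.adjustment_mean + eff.group_difference_mean)
        assert eff.overall_sd == pytest.approx(
            np.hypot(eff.adjustment_sd, eff.group_difference_sd)
        )

    def test_all_quiet_reference_bin_zero_adjustment(self):
        records = [
            make_record(f"r{i}", f"d{i}", 20.0, laeq=30.0 + i * 0.5) for i in range(10)
        ]
        eff = noise_effect(records)
        assert eff.adjustment_mean == 0.0
        assert eff.per_bin_delta == {35.0: 0.0}

    def test_no_monitored_records_rejected(self):
        with pytest.raises(ValueError):
            noise_effect([make_record()])

    def test_bin_deltas_vs_reference(self):
        records = [
            make_record(f"q{i}", f"dq{i}", 10.0, laeq=30.0) for i in range(20)
        ] + [
            make_record(f"n{i}", f"dn{i}", 20.0, laeq=52.0) for i in range(20)
        ]
        eff = noise_effect(records, n_boot=200)
        assert eff.per_bin_delta[35.0] == 0.0
        assert eff.per_bin_delta[50.0] == pytest.approx(10.0)
        assert eff.adjustment_mean == pytest.approx(5.0)


class TestCountryDifference:
    def test_headline_arithmetic(self):
        rel, absd = country_difference(37.8, 9.6)
        assert round(rel, 1) == 74.6
        assert round(absd, 1) == 28.2

    def test_equal_prevalences(self):
        assert country_difference(20.0, 20.0) == (0.0, 0.0)

    def test_self_similar(self):
        assert country_difference(50.0, 25.0) == (50.0, 25.0)

    def test_conventional_ratio_option(self):
        rel, _ = country_difference(50.0, 25.0, conventional=True)
        assert rel == pytest.approx(100.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            country_difference(0.0, 0.0)
        with pytest.raises(ValueError):
            country_difference(10.0, 20.0)


class TestMaskingBias:
    @staticmethod
    def lognormal_grid_sample(n: int, rng) -> np.ndarray:
        raw = rng.lognormal(mean=3.3, sigma=0.45, size=n) - 15.0
        return np.clip(np.round(raw / 5.0) * 5.0, -10.0, 100.0)

    def test_null_sample_near_zero_excess(self):
        rng = np.random.default_rng(31)
        x = self.lognormal_grid_sample(5000, rng)
        excess, params = masking_bias_score(x)
        assert params is not None
        assert excess < 0.03

    def test_constructed_spike_recovered(self):
        rng = np.random.default_rng(32)
        x = self.lognormal_grid_sample(5000, rng)
        n_spike = 1000  # move 20% of the mass onto {40, 45}
        x[:n_spike] = rng.choice([40.0, 45.0], size=n_spike)
        excess, _ = masking_bias_score(x)
        assert excess == pytest.approx(0.20, abs=0.05)

    def test_degenerate_all_spike(self):
        excess, params = masking_bias_score([40.0] * 200)
        assert excess == pytest.approx(1.0)
        assert params is None

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            masking_bias_score([40.0] * 99)


class TestHeterogeneity:
    def test_detects_country_differences(self):
        records = [
            record_with_ptas(40.0, 40.0, f"r{i}", f"d{i}", country="AA") for i in range(50)
        ] + [
            record_with_ptas(10.0, 10.0, f"s{i}", f"e{i}", country="AA") for i in range(50)
        ] + [
            record_with_ptas(40.0, 40.0, f"t{i}", f"f{i}", country="BB") for i in range(5)
        ] + [
            record_with_ptas(10.0, 10.0, f"u{i}", f"g{i}", country="BB") for i in range(95)
        ]
        stat, p = country_heterogeneity(records)
        assert p < 0.001
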