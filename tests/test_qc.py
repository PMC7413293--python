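"""Exclusion cascade, age consolidation, and the duration criterion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from crowdaudiometry.qc import (
    ExclusionFlow,
    apply_exclusions,
    consolidate_age,
    estimate_duration_threshold,
    fit_duration_model,
    is_complete,
)

from conftest import make_record


class TestCompleteness:
    def test_full_record_complete(self):
        assert is_complete(make_record())

    def test_missing_entry_incomplete(self):
        rec = make_record()
        del rec.thresholds[("left", 6000)]
        assert not is_complete(rec)

    def test_empty_record_incomplete(self):
        rec = make_record()
        rec.thresholds.clear()
        assert not is_complete(rec)


class TestConsolidateAge:
    @pytest.mark.parametrize(
        "entries,expected",
        [([39, 39], 39), ([39], 39), ([39, 41], None), ([], None), ([40, 40, 41], None)],
    )
    def test_rules(self, entries, expected):
        assert consolidate_age(entries) == expected


class TestDurationThreshold:
    def test_single_lognormal_recovers_closed_form_quantile(self):
        rng = np.random.default_rng(3)
        sample = np.exp(rng.normal(1.0, 0.5, size=10_000))
        expected = float(np.exp(1.0 + 0.5 * norm.ppf(0.99)))  # 8.70 s
        est = estimate_duration_threshold(sample, 0.99, mixture=False)
        assert est == pytest.approx(expected, rel=0.05)

    def test_median_level(self):
        rng = np.random.default_rng(3)
        sample = np.exp(rng.normal(1.0, 0.5, size=10_000))
        est = estimate_duration_threshold(sample, 0.5, mixture=False)
        assert est == pytest.approx(np.exp(1.0), rel=0.05)

    def test_mixture_recovers_short_component(self):
        """With a rushed subpopulation, the threshold is the 0.99
        quantile of the short lognormal component."""
        rng = np.random.default_rng(8)
        short = np.exp(rng.normal(0.7, 0.3, size=5_000))
        long = np.exp(rng.normal(2.8, 0.4, size=5_000))
        sample = np.concatenate([short, long])
        expected = float(np.exp(0.7 + 0.3 * norm.ppf(0.99)))
        est = estimate_duration_threshold(sample, 0.99, mixture=True)
        assert est == pytest.approx(expected, rel=0.10)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_duration_threshold([5.0] * 100)
        with pytest.raises(ValueError):
            estimate_duration_threshold([1.0, -2.0] * 50)
        with pytest.raises(ValueError):
            estimate_duration_threshold([1.0, 2.0])  # too few

    def test_duration_model_threshold(self):
        model = fit_duration_model(np.exp(np.random.default_rng(0).normal(1.0, 0.5, 1000)),
                                   mixture=False)
        assert model.threshold_seconds == pytest.approx(
            np.exp(model.mu_log + model.sigma_log * norm.ppf(0.99))
        )


class TestExclusionCascade:
    def test_toy_cascade_counts(self):
        incomplete = make_record("r1", "dA")
        del incomplete.thresholds[("left", 250)]
        records = [
            incomplete,
            make_record("r2", "dB", headphone_connected=False),
            make_record("r3", "dC", duration=2.0),
            make_record("r4", "dD"),
            make_record("r5", "dE"),
        ]
        retained, flow = apply_exclusions(records, 6.7)
        assert flow.as_dict() == {
            "n_total": 5,
            "n_incomplete": 1,
            "n_no_headphones": 1,
            "n_too_fast": 1,
            "n_device_duplicates": 0,
            "n_retained": 2,
        }
        assert {r.record_id for r in retained} == {"r4", "r5"}

    def test_first_failing_stage_attribution(self):
        rec = make_record("r1", "dA", duration=1.0, headphone_connected=False)
        del rec.thresholds[("left", 250)]
        _, flow = apply_exclusions([rec], 6.7)
        assert flow.n_incomplete == 1
        assert flow.n_no_headphones == 0
        assert flow.n_too_fast == 0

    def test_dedup_prefers_latest_with_age(self):
        records = [
            make_record("r1", "dA", timestamp=1.0, age_entries=[40]),
            make_record("r2", "dA", timestamp=2.0),
            make_record("r3", "dA", timestamp=3.0, age_entries=[35]),
        ]
        retained, _ = apply_exclusions(records, 1.0)
        assert [r.record_id for r in retained] == ["r3"]

    def test_dedup_age_preference_beats_recency(self):
        records = [
            make_record("r1", "dA", timestamp=1.0, age_entries=[40]),
            make_record("r2", "dA", timestamp=2.0),
        ]
        retained, _ = apply_exclusions(records, 1.0)
        assert [r.record_id for r in retained] == ["r1"]

    def test_conflicting_age_not_preferred(self):
        records = [
            make_record("r1", "dA", timestamp=1.0, age_entries=[40, 41]),
            make_record("r2", "dA", timestamp=0.5, age_entries=[38]),
        ]
        retained, _ = apply_exclusions(records, 1.0)
        assert [r.record_id for r in retained] == ["r2"]

    def test_timestamp_tie_broken_by_record_id(self):
        records = [
            make_record("r1", "dA", timestamp=1.0),
            make_record("r2", "dA", timestamp=1.0),
        ]
        retained, _ = apply_exclusions(records, 1.0)
        assert [r.record_id for r in retained] == ["r2"]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions([make_record()], 0.0)

    def test_flow_conservation_enforced(self):
        with pytest.raises(ValueError):
            ExclusionFlow(10, 1, 1, 1, 1, 5)
        with pytest.raises(ValueError):
            ExclusionFlow(4, -1, 1, 1, 1, 2)


@st.composite
def record_lists(draw):
    n = draw(st.integers(min_value=0, max_value=30))
    records = []
    for i in range(n):
        rec = make_record(
            record_id=f"r{i:03d}",
            device_id=f"d{draw(st.integers(0, 6))}",
            duration=draw(st.floats(0.5, 30.0, allow_nan=False)),
            timestamp=float(draw(st.integers(0, 10))),
            headphone_connected=draw(st.booleans()),
            age_entries=draw(
                st.lists(st.integers(min_value=18, max_value=90), max_size=2)
            ),
        )
        if draw(st.booleans()):
            del rec.thresholds[("left", 250)]
        records.append(rec)
    return records


class TestCascadeProperties:
    @given(records=record_lists(), threshold=st.floats(0.1, 40.0, allow_nan=False))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_conservation_and_uniqueness(self, records, threshold):
        retained, flow = apply_exclusions(records, threshold)
        assert flow.n_total == len(records)
        device_ids = [r.device_id for r in retained]
        assert len(device_ids) == len(set(device_ids))
        assert flow.n_retained == len(retained)

    @given(records=record_lists())
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_in_threshold(self, records):
        n_low = apply_exclusions(records, 1.0)[1].n_retained
        n_high = apply_exclusions(records, 20.0)[1].n_retained
        assert n_high <= n_low
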