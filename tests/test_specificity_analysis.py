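import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isrscape import (
    InsufficientDataError,
    R_GAS_KCAL,
    UsageError,
    ValidationError,
    VariantRecord,
    activity_from_energies,
    classify_hot_spots,
    correlate_panel,
    filter_by_reference,
    pearson_r,
)

from _oracles import brute_pearson


class TestPearsonR:
    def test_identity_is_perfectly_correlated(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_negative_affine_map_gives_minus_one(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(xs, [-2 * x + 5 for x in xs]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # covariance 5.5 over sqrt(5 * 8.75)
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 5]) == pytest.approx(
            5.5 / math.sqrt(5 * 8.75), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            pearson_r([1, 2, 3], [1, 2])

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=-100, max_value=100),
                st.floats(min_value=-100, max_value=100),
            ),
            min_size=3,
            max_size=50,
        )
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_loop(self, data):
        xs = [d[0] for d in data]
        ys = [d[1] for d in data]
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            with pytest.raises(InsufficientDataError):
                pearson_r(xs, ys)
            return
        assert pearson_r(xs, ys) == pytest.approx(brute_pearson(xs, ys), abs=1e-12)


class TestClassifyHotSpots:
    def test_published_style_low_isr_values_all_flagged(self):
        records = [
            VariantRecord("W83A", isr=3.503),
            VariantRecord("W164A", isr=2.985),
            VariantRecord("F208A", isr=3.827),
            VariantRecord("R211A", isr=3.386),
        ]
        calls = classify_hot_spots(records, threshold=4.0)
        assert all(c.is_hot_spot for c in calls)

    def test_threshold_boundary_is_strict(self):
        (call,) = classify_hot_spots([VariantRecord("X", isr=4.0)], threshold=4.0)
        assert not call.is_hot_spot

    def test_empty_panel_gives_empty_calls(self):
        assert classify_hot_spots([], threshold=4.0) == []

    def test_missing_isr_names_the_variant(self):
        with pytest.raises(ValidationError, match="W83A"):
            classify_hot_spots([VariantRecord("W83A")], threshold=4.0)

    def test_raising_the_threshold_never_unflags(self, small_panel):
        low = classify_hot_spots(small_panel, threshold=3.6)
        high = classify_hot_spots(small_panel, threshold=4.5)
        for a, b in zip(low, high):
            assert b.is_hot_spot or not a.is_hot_spot


class TestFilterByReference:
    def test_keeps_systems_within_tolerance_of_wild_type(self):
        records = [
            VariantRecord("WT", reaction_barrier=20.0, is_wild_type=True),
            VariantRecord("A", reaction_barrier=21.0),
            VariantRecord("B", reaction_barrier=22.0),
        ]
        kept = filter_by_reference(records, "barrier", 1.5)
        assert [r.variant_id for r in kept] == ["WT", "A"]

    def test_boundary_is_inclusive(self):
        records = [
            VariantRecord("WT", binding_affinity=-8.0, is_wild_type=True),
            VariantRecord("A", binding_affinity=-6.5),
        ]
        kept = filter_by_reference(records, "affinity", 1.5)
        assert len(kept) == 2

    def test_zero_tolerance_keeps_wild_type_and_exact_ties(self):
        records = [
            VariantRecord("WT", reaction_barrier=20.0, is_wild_type=True),
            VariantRecord("A", reaction_barrier=20.0),
            VariantRecord("B", reaction_barrier=20.1),
        ]
        kept = filter_by_reference(records, "barrier", 0.0)
        assert [r.variant_id for r in kept] == ["WT", "A"]

    def test_infinite_tolerance_is_the_identity(self, small_panel):
        assert filter_by_reference(small_panel, "barrier", math.inf) == small_panel

    def test_requires_exactly_one_wild_type(self):
        records = [VariantRecord("A", reaction_barrier=20.0)]
        with pytest.raises(ValidationError, match="wild-type"):
            filter_by_reference(records, "barrier", 1.5)

    def test_missing_field_names_the_variant(self):
        records = [
            VariantRecord("WT", reaction_barrier=20.0, is_wild_type=True),
            VariantRecord("A"),
        ]
        with pytest.raises(ValidationError, match="'A'"):
            filter_by_reference(records, "barrier", 1.5)


class TestCorrelatePanel:
    def test_exact_linear_relation(self):
        records = [
            VariantRecord(f"v{i}", isr=float(i), ln_activity=3.0 * i) for i in range(5)
        ]
        result = correlate_panel(records, "isr", "ln_activity")
        assert result.pearson_r == pytest.approx(1.0)
        assert result.slope == pytest.approx(3.0)
        assert result.intercept == pytest.approx(0.0, abs=1e-12)
        assert result.n_used == 5
        assert result.subset_rule == "none"

    def test_subset_changes_n_used_by_filtered_count(self, small_panel):
        full = correlate_panel(small_panel, "isr", "ln_activity")
        sub = correlate_panel(small_panel, "isr", "ln_activity", subset=("barrier", 1.0))
        removed = len(filter_by_reference(small_panel, "barrier", math.inf)) - len(
            filter_by_reference(small_panel, "barrier", 1.0)
        )
        assert full.n_used - sub.n_used == removed
        assert "barrier" in sub.subset_rule

    def test_missing_fields_are_dropped_pairwise(self, small_panel):
        small_panel.append(VariantRecord("noisr", ln_activity=-21.0))
        result = correlate_panel(small_panel, "isr", "ln_activity")
        assert result.n_used == 4

    def test_too_few_usable_records_rejected(self):
        records = [VariantRecord("a", isr=1.0, ln_activity=1.0),
                   VariantRecord("b", isr=2.0, ln_activity=2.0)]
        with pytest.raises(InsufficientDataError):
            correlate_panel(records, "isr", "ln_activity")

    def test_unknown_field_is_a_usage_error(self, small_panel):
        with pytest.raises(UsageError, match="unknown field"):
            correlate_panel(small_panel, "isr", "km")

    def test_default_synthetic_panel_lands_in_calibrated_band(self, default_panel):
        result = correlate_panel(default_panel.records, "isr", "ln_activity")
        assert 0.4 < result.pearson_r <= 1.0  # generous single-panel check


class TestActivityFromEnergies:
    def test_zero_energies_give_zero_activity(self):
        assert activity_from_energies(0.0, 0.0) == 0.0

    def test_closed_form_value(self):
        # -(15 - 5) / (R * 298.15) with R = 1.9872e-3 kcal/(mol K)
        expected = -10.0 / (R_GAS_KCAL * 298.15)
        got = activity_from_energies(-5.0, 15.0)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(-16.88, abs=0.01)

    def test_linear_in_the_barrier(self):
        base = activity_from_energies(-5.0, 15.0)
        lower = activity_from_energies(-5.0, 14.0)
        assert lower - base == pytest.approx(1.0 / (R_GAS_KCAL * 298.15))

    def test_iso_activity_trade_off(self):
        """Tighter binding exactly offsets a higher barrier at fixed activity."""
        a = activity_from_energies(-5.0, 15.0)
        b = activity_from_energies(-7.0, 17.0)
        assert a == pytest.approx(b)

    def test_offset_shifts_linearly(self):
        assert activity_from_energies(0.0, 0.0, offset=3.5) == 3.5

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(UsageError):
            activity_from_energies(-5.0, 15.0, temperature=0.0)
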