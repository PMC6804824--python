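"""Internal-standard quantification, odor-class aggregation, aroma grouping."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from scentvar.volatile import (
    DEFAULT_RULES,
    AromaProfile,
    InvalidPeakTable,
    OdorMap,
    PeakTable,
    RuleConfigError,
    aggregate_odor_classes,
    classify_aroma,
    quantify_content,
    select_major_compounds,
)


def make_table(entries, is_amount=0.8, is_peak=1000.0, weight=1.0):
    return PeakTable("cv", entries, "3-heptanone", is_amount, is_peak, weight)


class TestQuantifyContent:
    @pytest.mark.parametrize(
        "peak, is_amount, is_peak, weight, expected",
        [
            (0.0, 0.8, 1000.0, 1.0, 0.0),  # zero peak area
            (1000.0, 0.8, 1000.0, 1.0, 0.8),  # identity: equal areas, unit weight
            (2000.0, 0.5, 1000.0, 1.5, 0.666667),  # (2000*0.5/1000)/1.5
        ],
    )
    def test_formula(self, peak, is_amount, is_peak, weight, expected):
        profile = quantify_content(make_table([("X", peak)], is_amount, is_peak, weight))
        assert profile.contents["X"] == pytest.approx(expected, abs=1e-6)

    def test_empty_table_gives_empty_profile(self):
        profile = quantify_content(make_table([]))
        assert profile.contents == {} and profile.total_content == 0.0

    @pytest.mark.parametrize(
        "kwargs, named",
        [
            ({"is_peak": 0.0}, "is_peak_area"),
            ({"is_peak": -1.0}, "is_peak_area"),
            ({"weight": 0.0}, "sample_weight"),
            ({"is_amount": 0.0}, "is_amount"),
        ],
    )
    def test_invalid_inputs_rejected_naming_field(self, kwargs, named):
        full = {"is_amount": 0.8, "is_peak": 1000.0, "weight": 1.0, **kwargs}
        with pytest.raises(InvalidPeakTable, match=named):
            make_table([("X", 1.0)], full["is_amount"], full["is_peak"], full["weight"])

    def test_duplicate_compounds_rejected(self):
        with pytest.raises(InvalidPeakTable, match="duplicate"):
            make_table([("X", 1.0), ("X", 2.0)])

    @given(
        areas=st.lists(st.floats(0.1, 1e6), min_size=2, max_size=8),
        factor=st.floats(1.1, 100.0),
    )
    def test_linearity_and_scale_invariance(self, areas, factor):
        names = [f"c{i}" for i in range(len(areas))]
        base = quantify_content(make_table(list(zip(names, areas))))
        # doubling every compound area doubles contents, percents unchanged
        doubled = quantify_content(make_table([(n, a * 2) for n, a in zip(names, areas)]))
        for n in names:
            assert doubled.contents[n] == pytest.approx(2 * base.contents[n], rel=1e-9)
            assert doubled.percents[n] == pytest.approx(base.percents[n], rel=1e-9)
        # rescaling all areas *including the internal standard's* changes nothing
        scaled = quantify_content(
            make_table([(n, a * factor) for n, a in zip(names, areas)], is_peak=1000.0 * factor)
        )
        for n in names:
            assert scaled.contents[n] == pytest.approx(base.contents[n], rel=1e-9)

    @given(areas=st.lists(st.floats(0.1, 1e6), min_size=1, max_size=8))
    def test_percents_sum_to_100(self, areas):
        names = [f"c{i}" for i in range(len(areas))]
        profile = quantify_content(make_table(list(zip(names, areas))))
        assert math.isclose(sum(profile.percents.values()), 100.0, abs_tol=1e-6)


class TestSelectMajorCompounds:
    def test_both_above_threshold(self):
        p = quantify_content(make_table([("A", 500.0), ("B", 500.0)]))
        assert select_major_compounds([p], 10.0) == {"A", "B"}

    def test_boundary_is_strict(self):
        # X sits at exactly 10.0%: excluded under a strict > threshold
        p = quantify_content(make_table([("X", 100.0), ("Y", 900.0)]))
        assert p.percents["X"] == pytest.approx(10.0)
        assert select_major_compounds([p], 10.0) == {"Y"}

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            select_major_compounds([], 10.0)


class TestAggregateOdorClasses:
    def test_single_compound(self):
        p = quantify_content(make_table([("eucalyptol", 100.0)]))
        aroma = aggregate_odor_classes(p, OdorMap({"eucalyptol": "cool"}))
        assert aroma.class_percents == (0.0, 0.0, 100.0, 0.0, 0.0)

    def test_empty_profile(self):
        aroma = aggregate_odor_classes(quantify_content(make_table([])), OdorMap({}))
        assert aroma.class_percents == (0.0,) * 5 and aroma.total_content == 0.0

    def test_three_compound_summation(self):
        # two fruity at 30% + 40%, one herbal at 30%
        p = quantify_content(make_table([("f1", 300.0), ("f2", 400.0), ("h1", 300.0)]))
        odor = OdorMap({"f1": "fruity", "f2": "fruity", "h1": "herbal"})
        aroma = aggregate_odor_classes(p, odor)
        assert aroma.class_percents == pytest.approx((30.0, 70.0, 0.0, 0.0, 0.0))

    def test_unmapped_compounds_conserved(self):
        p = quantify_content(make_table([("known", 600.0), ("mystery", 400.0)]))
        aroma = aggregate_odor_classes(p, OdorMap({"known": "floral"}))
        assert aroma.unmapped == ["mystery"]
        assert sum(aroma.class_percents) + aroma.unmapped_percent == pytest.approx(100.0, abs=1e-6)

    def test_bad_class_label_rejected(self):
        with pytest.raises(ValueError):
            OdorMap({"x": "minty"})


class TestClassifyAroma:
    @pytest.mark.parametrize(
        "percents, total, expected",
        [
            # published cool-group cultivar (eucalyptol-dominated)
            ((9.36, 1.49, 66.30, 1.77, 0.18), 20.0, "cool"),
            # published fruity-group cultivar (ester-dominated, almost no cool)
            ((3.21, 87.69, 2.21, 1.72, 0.33), 20.0, "fruity"),
            # no emission at all
            ((0.0, 0.0, 0.0, 0.0, 0.0), 0.0, "faint"),
            # eucalyptol + ester blend
            ((4.38, 68.71, 21.67, 0.0, 0.0), 20.0, "musky"),
            # herbal + ester blend typical of the strongest-scented cultivars
            ((33.42, 36.78, 0.0, 4.43, 0.0), 20.0, "lily"),
        ],
    )
    def test_default_rules(self, percents, total, expected):
        aroma = AromaProfile("cv", percents, total)
        assert classify_aroma(aroma, DEFAULT_RULES) == expected

    def test_no_rule_matches(self):
        aroma = AromaProfile("cv", (10.0, 10.0, 10.0, 10.0, 10.0), 5.0)
        assert classify_aroma(aroma) == "unassigned"

    def test_unknown_field_is_config_error(self):
        aroma = AromaProfile("cv", (0.0,) * 5, 5.0)
        with pytest.raises(RuleConfigError):
            classify_aroma(aroma, [{"label": "x", "all": [["minty", "ge", 1.0]]}])

    def test_pure_function_of_class_percents(self):
        # permuting the compound order upstream cannot change the label
        entries = [("eucalyptol", 700.0), ("linalool", 100.0), ("myrcene", 100.0)]
        odor = OdorMap({"eucalyptol": "cool", "linalool": "floral", "myrcene": "herbal"})
        labels = set()
        for perm in (entries, entries[::-1], [entries[1], entries[2], entries[0]]):
            p = quantify_content(make_table(perm))
            labels.add(classify_aroma(aggregate_odor_classes(p, odor)))
        assert len(labels) == 1
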