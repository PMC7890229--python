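import pytest
from hypothesis import given, strategies as st

from dldpheno.errors import DataValidationError, UndefinedMetricError
from dldpheno.metrics import (
    ConfusionCounts,
    category_agreement,
    concordance,
    evaluate,
    format_percent,
    inclusion_confusion,
    overall_correctness,
    percent_agreement,
    ppv_npv,
    prevalence,
    tnr,
    tpr,
)


class TestInclusionConfusion:
    def test_perfect_agreement(self):
        ref = {f"r{i}": i < 6 for i in range(10)}
        counts = inclusion_confusion(ref, ref)
        assert (counts.a, counts.b, counts.c, counts.d) == (6, 4, 0, 0)

    def test_fully_inverted(self):
        ref = {f"r{i}": i < 6 for i in range(10)}
        pred = {k: not v for k, v in ref.items()}
        counts = inclusion_confusion(pred, ref)
        assert counts.a == counts.b == 0
        assert counts.c + counts.d == 10

    def test_hand_enumerable_example(self):
        pred = {"x": True, "y": True, "z": False}
        ref = {"x": True, "y": False, "z": False}
        counts = inclusion_confusion(pred, ref)
        assert (counts.a, counts.b, counts.c, counts.d) == (1, 1, 1, 0)

    def test_mismatched_keys(self):
        with pytest.raises(DataValidationError):
            inclusion_confusion({"x": True}, {"y": True})

    @given(
        st.dictionaries(
            st.text(alphabet="abcdef", min_size=1, max_size=3),
            st.tuples(st.booleans(), st.booleans()),
            min_size=1,
        )
    )
    def test_counts_conserve_n(self, joint):
        pred = {k: v[0] for k, v in joint.items()}
        ref = {k: v[1] for k, v in joint.items()}
        assert inclusion_confusion(pred, ref).n == len(joint)


class TestRatesAndConcordance:
    def test_tpr_all_inclusions_captured(self):
        # every manually included record also captured by the algorithm
        assert tpr(ConfusionCounts(a=469, b=0, c=0, d=0)) == 1.0

    @pytest.mark.parametrize(
        "counts, fn, expected",
        [
            (ConfusionCounts(a=0, b=0, c=0, d=5), tpr, 0.0),
            (ConfusionCounts(a=0, b=87, c=13, d=0), tnr, 0.87),
        ],
    )
    def test_simple_divisions(self, counts, fn, expected):
        assert fn(counts) == pytest.approx(expected)

    def test_inclusion_concordance_discovery_counts(self):
        counts = ConfusionCounts(a=469, b=496, c=8, d=0)
        value = concordance(counts, "inclusion")
        assert value == pytest.approx(469 / 477)
        assert format_percent(value) == "98%"

    def test_exclusion_concordance_discovery_counts(self):
        counts = ConfusionCounts(a=469, b=496, c=8, d=0)
        assert concordance(counts, "exclusion") == 1.0
        assert format_percent(1.0) == "100%"

    def test_exclusion_concordance_is_one_whenever_d_is_zero(self):
        for b, c in [(1, 0), (50, 3), (496, 8)]:
            assert concordance(ConfusionCounts(a=9, b=b, c=c, d=0), "exclusion") == 1.0

    def test_unknown_side(self):
        with pytest.raises(DataValidationError):
            concordance(ConfusionCounts(1, 1, 1, 1), "sideways")

    @pytest.mark.parametrize(
        "fn", [tpr, tnr, lambda c: concordance(c, "inclusion"), ppv_npv]
    )
    def test_zero_denominators_are_undefined(self, fn):
        with pytest.raises(UndefinedMetricError):
            fn(ConfusionCounts(a=0, b=0, c=0, d=0))


class TestPredictiveValues:
    def test_ppv(self):
        ppv, _ = ppv_npv(ConfusionCounts(a=19, b=1, c=1, d=1))
        assert ppv == pytest.approx(0.95)

    def test_npv_replication_ratio(self):
        _, npv = ppv_npv(ConfusionCounts(a=1, b=9, c=1, d=5))
        assert npv == pytest.approx(9 / 14)
        assert format_percent(npv) == "64%"

    def test_no_errors_gives_unity(self):
        assert ppv_npv(ConfusionCounts(a=3, b=2, c=0, d=0)) == (1.0, 1.0)


class TestCategoryAgreement:
    def test_three_of_four(self):
        ref = {"a": 3, "b": 3, "c": 3, "d": 3, "e": 1}
        pred = {"a": 3, "b": 3, "c": 3, "d": 1, "e": 1}
        assert category_agreement(pred, ref, 3) == 0.75

    def test_perfect_prediction(self):
        ref = {"a": 1, "b": 2, "c": 3, "d": 4}
        for k in (1, 2, 3, 4):
            assert category_agreement(ref, ref, k) == 1.0

    def test_missing_category_undefined(self):
        ref = {"a": 1}
        with pytest.raises(UndefinedMetricError):
            category_agreement(ref, ref, 4)


class TestOverallCorrectnessAndAgreement:
    def test_discovery_sample_ratio(self):
        ref = {f"r{i}": 1 for i in range(973)}
        pred = {rid: (1 if i < 949 else 2) for i, rid in enumerate(ref)}
        value = overall_correctness(pred, ref)
        assert value == pytest.approx(949 / 973)
        assert format_percent(value) == "98%"

    def test_identity_and_disjoint(self):
        ref = {"a": 1, "b": 2}
        assert overall_correctness(ref, ref) == 1.0
        assert overall_correctness({"a": 3, "b": 4}, ref) == 0.0

    def test_percent_agreement_symmetry(self):
        x = {"a": 1, "b": 2, "c": 3}
        y = {"a": 1, "b": 3, "c": 3}
        assert percent_agreement(x, y) == percent_agreement(y, x) == pytest.approx(2 / 3)

    def test_percent_agreement_formula(self):
        x = {f"r{i}": 1 for i in range(100)}
        y = {rid: (1 if i < 93 else 2) for i, rid in enumerate(x)}
        assert percent_agreement(x, y) == pytest.approx(0.93)


class TestPrevalence:
    def test_replication_sample(self):
        value = prevalence(6013, 561884)
        assert value == pytest.approx(6013 / 561884)
        assert format_percent(value, decimals=1) == "1.1%"

    @pytest.mark.parametrize("n, total, expected", [(0, 1000, 0.0), (1000, 1000, 1.0)])
    def test_bounds(self, n, total, expected):
        assert prevalence(n, total) == expected

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedMetricError):
            prevalence(0, 0)


class TestRendering:
    @pytest.mark.parametrize(
        "fraction, decimals, rendered",
        [
            (0.9753, 0, "98%"),
            (0.985, 0, "99%"),   # half rounds away from zero
            (0.005, 0, "1%"),
            (0.0107, 1, "1.1%"),
            (1.0, 0, "100%"),
            (0.0, 0, "0%"),
        ],
    )
    def test_round_half_away_from_zero(self, fraction, decimals, rendered):
        assert format_percent(fraction, decimals) == rendered


class TestEvaluate:
    def test_full_report_with_gold_subset(self):
        ref = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 2}
        pred = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 3}
        report = evaluate(pred, ref, gold={"a": 1, "c": 4})
        assert (report.confusion.a, report.confusion.b) == (2, 2)
        assert report.confusion.d == 1
        assert report.tpr_by_category[1] == 1.0
        assert report.tpr_by_category[2] == 0.5
        assert report.concordance_exclusion == pytest.approx(2 / 3)
        assert report.overall_correctness == pytest.approx(4 / 5)
        assert report.ppv == 1.0 and report.npv == 1.0

    def test_unclassified_records_never_count_as_included(self):
        ref = {"a": 1, "b": 3}
        pred = {"a": 0, "b": 0}
        report = evaluate(pred, ref)
        assert report.confusion.d == 1  # the label-included record was excluded
        assert report.confusion.b == 1

    def test_undefined_metrics_reported_as_none(self):
        ref = {"a": 1, "b": 2}
        report = evaluate(ref, ref)
        assert report.tnr_by_category[3] is None
        assert report.concordance_exclusion is None
        rendered = report.to_dict()["rendered"]
        assert rendered["concordance_exclusion"] is None
        assert rendered["overall_correctness"] == "100%"
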