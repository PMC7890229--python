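import pytest
from hypothesis import given, strategies as st

from dldpheno.errors import DataValidationError
from dldpheno.model import CodeCriterion, first_ld_age
from dldpheno.simulate import SimulationConfig, generate_cohort
from dldpheno.training import (
    CategoryFilters,
    LabeledCohort,
    extract_raw_code_lists,
    systematic_subtraction,
    train_filters,
)

from conftest import A, B, C, D, E, LD, make_record

code_sets = st.sets(
    st.sampled_from(["A", "B", "C", "D", "E", "F", "G", "H", "L"]), max_size=9
)


class TestExtractRawCodeLists:
    def test_union_per_category(self):
        cohort = LabeledCohort(
            records=[
                make_record("x", [(LD, 10), (A, 20)]),
                make_record("y", [(LD, 10), (B, 20)]),
            ],
            labels={"x": 1, "y": 1},
        )
        r1, r2, r3, r4 = extract_raw_code_lists(cohort)
        assert r1 == {LD, A, B}
        assert r2 == r3 == r4 == frozenset()

    def test_category4_date_restriction_is_inclusive(self):
        # codes strictly after the first LD code are dropped; same-day kept
        cohort = LabeledCohort(
            records=[make_record("t", [(E, 100), (LD, 200), (A, 200), (B, 300)])],
            labels={"t": 4},
        )
        _, _, _, r4 = extract_raw_code_lists(cohort)
        assert r4 == {E, LD, A}

    def test_category4_strict_variant(self):
        cohort = LabeledCohort(
            records=[make_record("t", [(E, 100), (LD, 200), (A, 200)])],
            labels={"t": 4},
        )
        _, _, _, r4 = extract_raw_code_lists(cohort, cat4_inclusive=False)
        assert r4 == {E}

    def test_empty_category_warns(self, toy_cohort, caplog):
        cohort = LabeledCohort(
            records=[make_record("x", [(LD, 10)])], labels={"x": 1}
        )
        with caplog.at_level("WARNING"):
            _, _, r3, _ = extract_raw_code_lists(cohort)
        assert r3 == frozenset()
        assert any("category 3" in m for m in caplog.messages)

    def test_empty_cohort_rejected(self):
        cohort = LabeledCohort(records=[], labels={})
        with pytest.raises(DataValidationError):
            extract_raw_code_lists(cohort)


class TestSystematicSubtraction:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (
                ({"A", "B", "L"}, {"A", "C", "L"}, {"C", "D"}, {"D", "E"}),
                ({"A", "B", "L"}, {"C"}, {"D"}, {"E"}),
            ),
            (
                ({"A"}, {"B"}, {"C"}, {"D"}),
                ({"A"}, {"B"}, {"C"}, {"D"}),  # disjoint inputs pass through
            ),
            (
                ({"X"}, {"X"}, {"X"}, {"X"}),
                ({"X"}, set(), set(), set()),  # full overlap collapses
            ),
        ],
    )
    def test_worked_examples(self, raw, expected):
        filters = systematic_subtraction(*map(frozenset, raw))
        got = tuple(filters.filter_for(k) for k in (1, 2, 3, 4))
        assert got == tuple(map(frozenset, expected))

    @given(r1=code_sets, r2=code_sets, r3=code_sets, r4=code_sets)
    def test_disjointness_and_conservation(self, r1, r2, r3, r4):
        f = systematic_subtraction(*map(frozenset, (r1, r2, r3, r4)))
        sets = [f.filter_for(k) for k in (1, 2, 3, 4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not sets[i] & sets[j]
        assert sets[0] | sets[1] | sets[2] == frozenset(r1 | r2 | r3)
        assert sets[3] <= frozenset(r4)

    @given(r1=code_sets, r2=code_sets, r3=code_sets, r4=code_sets)
    def test_subtracting_filters_equals_subtracting_raw_lists(self, r1, r2, r3, r4):
        # independent oracle: subtract previously computed filters instead
        f = systematic_subtraction(*map(frozenset, (r1, r2, r3, r4)))
        f1 = frozenset(r1)
        f2 = frozenset(r2) - f1
        f3 = frozenset(r3) - f2 - f1
        f4 = frozenset(r4) - f3 - f2 - f1
        assert (f.filter_1, f.filter_2, f.filter_3, f.filter_4) == (f1, f2, f3, f4)


class TestTrainFilters:
    def test_toy_cohort(self, toy_filters):
        assert toy_filters.filter_1 == {A, B, LD}
        assert toy_filters.filter_2 == {C}
        assert toy_filters.filter_3 == {D}
        assert toy_filters.filter_4 == {E}
        prov = toy_filters.provenance
        assert prov["records_per_category"] == {"1": 1, "2": 1, "3": 1, "4": 1}
        assert prov["filter_code_counts"] == {"1": 3, "2": 1, "3": 1, "4": 1}

    def test_ld_codes_land_in_filter_1(self, toy_filters):
        assert LD in toy_filters.filter_1

    def test_record_without_ld_code_rejected(self):
        cohort = LabeledCohort(
            records=[make_record("x", [(A, 10)])], labels={"x": 1}
        )
        with pytest.raises(DataValidationError):
            train_filters(cohort)

    def test_label_record_alignment_enforced(self):
        record = make_record("x", [(LD, 10)])
        with pytest.raises(DataValidationError):
            LabeledCohort(records=[record], labels={})
        with pytest.raises(DataValidationError):
            LabeledCohort(records=[record], labels={"x": 1, "ghost": 2})

    def test_filters_cover_observed_pool_codes_without_leakage(self):
        config = SimulationConfig(leakage=0.0, seed=23)
        records, labels, truth = generate_cohort(config)
        qualifying = [r for r in records if r.record_id in labels]
        cohort = LabeledCohort(
            records=qualifying, labels={r.record_id: labels[r.record_id] for r in qualifying}
        )
        filters = train_filters(cohort)
        pools = truth["pools"]
        ld = CodeCriterion(exact_codes=frozenset(pools["ld_codes"]))

        by_cat = cohort.by_category()
        for k, pool_name in ((2, "cat2_pool"), (3, "cat3_pool")):
            observed = set()
            for record in by_cat[k]:
                observed |= record.codes & set(pools[pool_name])
            assert observed <= filters.filter_for(k)
        observed4 = set()
        for record in by_cat[4]:
            onset = first_ld_age(record, ld)
            observed4 |= {
                e.code
                for e in record.events
                if e.age_days <= onset and e.code in set(pools["cat4_trauma_pool"])
            }
        assert observed4 <= filters.filter_4

    def test_non_disjoint_filters_cannot_be_constructed(self):
        with pytest.raises(DataValidationError):
            CategoryFilters(
                filter_1=frozenset({"A"}),
                filter_2=frozenset({"A"}),
                filter_3=frozenset(),
                filter_4=frozenset(),
                ld_criterion=CodeCriterion(exact_codes={LD}),
            )
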