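"""The agreement statistic against an independent scalar oracle, plus
classification, group summaries and optimal-scenario selection."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aecpg_align import (
    CatalogMismatchError,
    DesireMatrix,
    SupplyMatrix,
    UndefinedAgreementError,
    ValidationError,
    agreement_score,
    classify,
    dea,
    group_agreement,
    optimal_scenario,
    pa,
    score_record,
)

from conftest import make_record, make_supply

SUPPLY_LEVELS = (0.0, 0.5, 1.0)
DESIRE_LEVELS = (0.0, 0.5, 1.0)
WEIGHT_LEVELS = (0, 1, 2)


def oracle(e, d, w):
    """Scalar brute-force evaluation of the statistic, no numpy."""
    total_diff = 0.0
    total_weight = 0.0
    for ei, di, wi in zip(e, d, w):
        total_diff += abs(ei - di) * wi
        total_weight += wi
    agreement = (
        100.0 * (total_weight - total_diff) / total_weight
        if total_weight > 0
        else None
    )
    return total_diff, total_weight, agreement


class TestOracleEquivalence:
    def test_full_enumeration_two_goods(self):
        """Every (e, d, w) combination over a 2-good catalog matches the
        oracle exactly (729 combos; PA = 0 ones must raise instead)."""
        per_good = list(
            itertools.product(SUPPLY_LEVELS, DESIRE_LEVELS, WEIGHT_LEVELS)
        )
        n_checked = 0
        for combo in itertools.product(per_good, per_good):
            e = [g[0] for g in combo]
            d = [g[1] for g in combo]
            w = [g[2] for g in combo]
            exp_dea, exp_pa, exp_agr = oracle(e, d, w)
            assert dea(e, d, w) == exp_dea
            assert pa(w) == exp_pa
            if exp_pa == 0:
                with pytest.raises(UndefinedAgreementError):
                    agreement_score(e, d, w)
            else:
                assert agreement_score(e, d, w) == exp_agr
                n_checked += 1
        # 81 combos weight both goods zero (9 e,d pairs per zero-weight good)
        assert n_checked == 729 - 81

    @settings(max_examples=500, derandomize=True)
    @given(st.data())
    def test_random_instances_bounded_and_scale_invariant(self, data):
        n = data.draw(st.integers(1, 9))
        e = data.draw(st.lists(st.sampled_from(SUPPLY_LEVELS), min_size=n, max_size=n))
        d = data.draw(st.lists(st.sampled_from(DESIRE_LEVELS), min_size=n, max_size=n))
        w = data.draw(st.lists(st.sampled_from(WEIGHT_LEVELS), min_size=n, max_size=n))
        if sum(w) == 0:
            w[data.draw(st.integers(0, n - 1))] = 1
        a = agreement_score(e, d, w)
        assert 0.0 <= a <= 100.0
        k = data.draw(st.sampled_from([0.5, 2.0, 7.0]))
        assert agreement_score(e, d, [wi * k for wi in w]) == pytest.approx(a)
        # permutation invariance over good order
        perm = data.draw(st.permutations(range(n)))
        assert agreement_score(
            [e[i] for i in perm], [d[i] for i in perm], [w[i] for i in perm]
        ) == pytest.approx(a)

    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_hundred_iff_match_on_weighted_goods(self, data):
        n = data.draw(st.integers(1, 6))
        e = data.draw(st.lists(st.sampled_from(SUPPLY_LEVELS), min_size=n, max_size=n))
        d = data.draw(st.lists(st.sampled_from(DESIRE_LEVELS), min_size=n, max_size=n))
        w = data.draw(st.lists(st.sampled_from(WEIGHT_LEVELS), min_size=n, max_size=n))
        if sum(w) == 0:
            w[0] = 1
        match = all(ei == di for ei, di, wi in zip(e, d, w) if wi > 0)
        assert (agreement_score(e, d, w) == 100.0) == match


class TestWorkedExamples:
    def test_perfect_match_is_hundred(self):
        r = make_record([1, 0.5, 0], [2, 1, 1])
        s = make_supply([1, 0.5, 0])
        assert agreement_score(s, r) == 100.0

    def test_maximal_mismatch_is_zero(self):
        r = make_record([0, 0, 1], [1, 0, 2])
        s = make_supply([1, 1, 0])
        assert agreement_score(s, r) == 0.0

    def test_dea_three_pa_four_gives_25(self):
        # |1-0|*2 + |0.5-0.5|*1 + |0-1|*1 = 3 over PA 4
        e = [1, 0.5, 0, 0, 0, 0, 0, 0, 0]
        d = [0, 0.5, 1, 0, 0, 0, 0, 0, 0]
        w = [2, 1, 1, 0, 0, 0, 0, 0, 0]
        assert dea(e, d, w) == 3.0
        assert pa(w) == 4.0
        assert agreement_score(e, d, w) == 25.0
        assert classify(25.0) == "disagreement"

    def test_single_half_term(self):
        assert dea([0.5], [0.0], [2]) == 1.0

    def test_record_interface_and_result(self):
        r = make_record([1, 0, 0], [2, 1, 0], "s1", "NGOs")
        s = make_supply([0.5, 0, 0], "regional")
        res = score_record(s, r)
        assert res.dea == 1.0 and res.pa == 3.0
        assert res.agreement == pytest.approx(100 * 2 / 3)
        assert res.class_label == "agreement"
        assert (res.stakeholder_id, res.scenario_id) == ("s1", "regional")

    def test_catalog_length_mismatch(self):
        with pytest.raises(CatalogMismatchError):
            dea([1, 0], [1, 0, 0], [1, 1, 1])


class TestClassify:
    @pytest.mark.parametrize(
        "a,label",
        [
            (0, "strong_disagreement"),
            (19.9, "strong_disagreement"),
            (20, "disagreement"),
            (25, "disagreement"),
            (40, "moderate"),
            (60, "agreement"),
            (80, "agreement"),  # the 60-80 band is closed at 80
            (80.1, "high_agreement"),
            (100, "high_agreement"),
        ],
    )
    def test_default_bands(self, a, label):
        assert classify(a) == label

    def test_alternative_policy_moves_80(self):
        assert classify(80, policy="high_from_80") == "high_agreement"
        assert classify(79.9, policy="high_from_80") == "agreement"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify(101)
        with pytest.raises(ValidationError):
            classify(-0.1)


class TestGroupAgreement:
    def _matrix(self, catalog3):
        # NGO agrees fully (e matches d on weighted goods); Banks half
        records = (
            make_record([1, 0, 0], [2, 0, 0], "n1", "NGOs"),
            make_record([1, 1, 0], [1, 1, 0], "b1", "Banks"),
            make_record([0, 1, 0], [0, 2, 0], "b2", "Banks"),
        )
        return DesireMatrix(catalog=catalog3, records=records)

    def test_group_means_and_overall_modes(self, catalog3):
        m = self._matrix(catalog3)
        s = make_supply([1, 0, 0], "scn")
        # agreements: n1 = 100; b1 = 100*(2-1)/2 = 50; b2 = 0
        by_stakeholder = group_agreement(m, s, "stakeholder_mean")
        assert by_stakeholder.per_group.loc["NGOs", "mean"] == 100.0
        assert by_stakeholder.per_group.loc["Banks", "mean"] == 25.0
        assert by_stakeholder.overall == 50  # (100+50+0)/3
        by_group = group_agreement(m, s, "group_mean_of_means")
        assert by_group.overall == 63  # (100 + 25)/2 = 62.5, half-up

    def test_single_stakeholder_group(self, catalog3):
        m = DesireMatrix(
            catalog=catalog3,
            records=(make_record([0, 0, 1], [1, 0, 1], "solo", "Funds"),),
        )
        s = make_supply([1, 0, 1], "scn")
        summ = group_agreement(m, s)
        assert summ.per_group.loc["Funds", "mean"] == 50.0
        assert summ.per_group.loc["Funds", "n"] == 1
        assert summ.overall == 50

    def test_group_mean_rounded_one_decimal(self, catalog3):
        # agreements 100 and 100*(3-1)/3 = 66.667 -> mean 83.333 -> 83.3
        records = (
            make_record([1, 0, 0], [1, 0, 0], "a", "G"),
            make_record([1, 1, 1], [1, 1, 1], "b", "G"),
        )
        m = DesireMatrix(catalog=catalog3, records=records)
        s = make_supply([1, 1, 0], "scn")
        summ = group_agreement(m, s)
        assert summ.per_group.loc["G", "mean"] == 83.3
        assert summ.per_group.loc["G", "min"] == 66.7
        assert summ.per_group.loc["G", "max"] == 100.0


class TestOptimalScenario:
    def test_argmax_and_tie_warning(self, catalog3):
        m = DesireMatrix(
            catalog=catalog3,
            records=(make_record([1, 0, 0], [1, 0, 0], "a", "G"),),
        )
        sm = SupplyMatrix(
            catalog=catalog3,
            scenarios=(
                make_supply([0, 0, 0], "bad"),
                make_supply([1, 0, 0], "good"),
            ),
        )
        assert optimal_scenario(sm, m) == "good"
        tie = SupplyMatrix(
            catalog=catalog3,
            scenarios=(make_supply([1, 0, 0], "x"), make_supply([1, 0.5, 0], "y")),
        )
        with pytest.warns(UserWarning, match="tie"):
            assert optimal_scenario(tie, m) == "x"

    def test_single_scenario(self, catalog3):
        m = DesireMatrix(
            catalog=catalog3,
            records=(make_record([1, 0, 0], [1, 0, 0], "a", "G"),),
        )
        sm = SupplyMatrix(catalog=catalog3, scenarios=(make_supply([0, 0, 0], "only"),))
        assert optimal_scenario(sm, m) == "only"
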