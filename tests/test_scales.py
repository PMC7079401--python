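import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressproc.scales import (
    SubjectRecord,
    apply_eligibility,
    classify_muac,
    cronbach_alpha,
    score_epds,
    score_osss3,
    score_pci4,
)

epds_items = st.lists(st.integers(0, 3), min_size=10, max_size=10)


class TestEpds:
    @pytest.mark.parametrize(
        "items,total,category",
        [
            ([0] * 10, 0, "none"),
            ([3] * 10, 30, "excluded_high"),
            ([2] * 5 + [0] * 5, 10, "none"),
            ([2] * 6 + [0] * 4, 12, "possible_depression"),
            ([2] * 8 + [0] * 2, 16, "possible_depression"),
            ([2] * 8 + [1, 0], 17, "excluded_high"),
        ],
    )
    def test_cutoffs(self, items, total, category):
        score = score_epds(items)
        assert score.total == total
        assert score.category == category

    def test_self_harm_flag_from_item_ten(self):
        items = [0] * 9 + [1]
        score = score_epds(items)
        assert score.has_flag("self_harm_flag")
        assert score.has_flag("referral_flag")  # flag even with a total of 1
        assert not score_epds([1] + [0] * 9).has_flag("self_harm_flag")

    def test_referral_threshold_is_13_not_12(self):
        no_harm = [2, 2, 2, 2, 2, 2, 0, 0, 0, 0]  # total 12
        assert not score_epds(no_harm).has_flag("referral_flag")
        assert score_epds([2] * 6 + [1, 0, 0, 0]).has_flag("referral_flag")  # 13

    @pytest.mark.parametrize(
        "bad", [[0] * 9, [0] * 11, [0] * 9 + [4], [0] * 9 + [-1], [0] * 9 + [None]]
    )
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            score_epds(bad)

    @given(epds_items, st.integers(0, 9))
    def test_total_monotone_in_each_item(self, items, idx):
        if items[idx] == 3:
            items[idx] = 2
        bumped = list(items)
        bumped[idx] += 1
        assert score_epds(bumped).total == score_epds(items).total + 1


class TestOsss3:
    def test_minimum_is_poor(self):
        s = score_osss3([1, 1, 1])
        assert s.total == 3 and s.category == "poor"

    def test_boundary_at_nine(self):
        assert score_osss3([4, 2, 3]).category == "moderate_to_strong"  # 9
        assert score_osss3([4, 2, 2]).category == "poor"  # 8
        assert score_osss3([4, 5, 5]).total == 14

    @pytest.mark.parametrize("bad", [[5, 1, 1], [0, 1, 1], [1, 6, 1], [1, 1], [1, 1, None]])
    def test_rejects_out_of_scale(self, bad):
        with pytest.raises(ValueError):
            score_osss3(bad)


def test_pci4_totals():
    assert score_pci4([0, 0, 0, 0]).total == 0
    assert score_pci4([3, 3, 3, 3]).total == 12
    assert score_pci4([1, 2, 3, 0]).category is None
    with pytest.raises(ValueError):
        score_pci4([1, 2, 3])


class TestMuac:
    @pytest.mark.parametrize(
        "value,label",
        [(20.0, "normal"), (18.0, "normal"), (22.0, "normal"),
         (24.1, "underweight"), (22.5, "underweight"), (31.0, "underweight"),
         (17.0, "out_of_range"), (22.2, "out_of_range"), (31.5, "out_of_range")],
    )
    def test_printed_rule(self, value, label):
        assert classify_muac(value) == label

    def test_conventional_ruleset_swaps_labels(self):
        assert classify_muac(20.0, "conventional") == "underweight"
        assert classify_muac(24.1, "conventional") == "normal"

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_muac(0.0)


class TestCronbachAlpha:
    def test_duplicated_columns_give_one(self, rng):
        col = rng.normal(size=30)
        assert cronbach_alpha(np.column_stack([col, col, col])) == pytest.approx(1.0)

    def test_toy_matrix_matches_direct_formula(self):
        x = np.array([[0, 1, 2], [1, 1, 3], [2, 3, 3], [3, 3, 1]], dtype=float)
        # independent evaluation: population variances of items and total
        k = 3
        item_vars = [np.mean((c - c.mean()) ** 2) for c in x.T]
        total = x.sum(axis=1)
        total_var = np.mean((total - total.mean()) ** 2)
        expected = k / (k - 1) * (1 - sum(item_vars) / total_var)
        assert cronbach_alpha(x) == pytest.approx(expected, abs=1e-12)

    def test_shift_invariance(self, rng):
        x = rng.integers(0, 4, size=(50, 5)).astype(float)
        assert cronbach_alpha(x + 7.0) == pytest.approx(cronbach_alpha(x), abs=1e-10)

    def test_zero_total_variance_signals_nan(self):
        x = np.zeros((5, 3))
        assert math.isnan(cronbach_alpha(x))

    def test_rejects_small_or_missing(self, rng):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 3)))
        x = rng.normal(size=(10, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            cronbach_alpha(x)


def _record(i, epds):
    return SubjectRecord(
        subject_id=f"S{i}", epds_items=epds, osss3_items=[3, 4, 4],
        pci4_items=[2, 2, 2, 2], partner_support=4, marital_agreement=3,
        food_access_difficulty=0, pregnancy_intention="planned",
        fear_of_birth=0, history_cmd=0, gestational_weeks=30,
        muac_cm=24.0, cluster_id="k1",
    )


class TestEligibility:
    def test_exclusion_partitions_exactly(self):
        # 940-style cohort: 24 records at or above the exclusion cutoff
        records = [_record(i, [1] * 10) for i in range(916)]
        records += [_record(900 + i, [2] * 8 + [1, 0]) for i in range(24)]
        analysis, excluded, referral = apply_eligibility(records)
        assert len(analysis) == 916
        assert len(excluded) == 24
        assert len(analysis) + len(excluded) == len(records)
        assert {r.subject_id for r in excluded}.issubset({r.subject_id for r in referral})

    def test_empty_input(self):
        assert apply_eligibility([]) == ([], [], [])

    def test_all_low_scores_refer_nobody(self):
        records = [_record(i, [1, 0] * 5) for i in range(10)]
        analysis, excluded, referral = apply_eligibility(records)
        assert len(analysis) == 10 and not excluded and not referral

    def test_record_validation(self):
        rec = _record(0, [1] * 10)
        rec.validate()
        rec.gestational_weeks = 8
        with pytest.raises(ValueError):
            rec.validate()
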