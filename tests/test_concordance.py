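"""The statistical cascade: ratios, t-test, ANOVA, rescue, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaconcord.concordance import (
    Classification,
    Direction,
    SummaryTable,
    classify,
    direction_discordant,
    leave_one_out_rescue,
    one_way_anova,
    ratio_replicates,
    round_half_away,
    student_t_test,
    TTestResult,
)

# ---------------------------------------------------------------------------
# independent textbook oracles
# ---------------------------------------------------------------------------


def naive_pooled_t(a, b):
    """Pooled-variance two-sample t from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def naive_anova_f(groups):
    """Between/within F from the definitional sums of squares."""
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    k, n = len(groups), sum(len(g) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------


class TestRatioReplicates:
    def test_constant_ratio(self):
        rs = ratio_replicates([2, 2, 2], [1, 1, 1])
        assert rs.ratios == (2.0, 2.0, 2.0)
        assert rs.mean == 2.0 and rs.sd == 0.0

    def test_identity(self):
        rs = ratio_replicates([1, 2, 3], [1, 2, 3])
        assert rs.ratios == (1.0, 1.0, 1.0)
        assert rs.mean == 1.0

    def test_missing_replicate_pairs_by_index(self):
        # replicate 3 missing in HT29: pairs are (2/1, 4/2)
        rs = ratio_replicates([2, 4, None], [1, 2, 1])
        assert rs.ratios == (2.0, 2.0)
        assert rs.mean == 2.0

    def test_zero_denominator_pair_dropped(self):
        rs = ratio_replicates([2, 4, 6], [0, 2, 3])
        assert rs.ratios == (2.0, 2.0)

    def test_fewer_than_two_pairs_excludes_method(self):
        assert ratio_replicates([2, None, None], [1, 1, 1]) is None
        assert ratio_replicates([2, 4, 6], [0, 0, 3]) is None

    def test_ratio_of_means_mode(self):
        rs = ratio_replicates([2, 4, 6], [1, 2, 3], mode="ratio_of_means")
        assert rs.ratios == (2.0,)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------


class TestStudentT:
    def test_identical_groups(self):
        res = student_t_test([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant
        assert res.direction is Direction.NONE

    def test_hand_computed_example(self):
        res = student_t_test([10, 12, 11], [20, 22, 21])
        assert res.t_statistic == pytest.approx(-12.247448, abs=1e-5)
        assert res.dof == 4
        assert res.p_value < 0.001
        assert res.significant

    def test_matches_naive_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.normal(0, 1, 3), rng.normal(0.5, 2, 3)
            res = student_t_test(a, b)
            assert res.t_statistic == pytest.approx(naive_pooled_t(a, b), abs=1e-10)

    def test_zero_variance_conventions(self):
        equal = student_t_test([2, 2, 2], [2, 2, 2])
        assert (equal.t_statistic, equal.p_value) == (0.0, 1.0)
        unequal = student_t_test([3, 3, 3], [2, 2, 2])
        assert unequal.p_value == 0.0
        assert math.isinf(unequal.t_statistic)

    def test_direction_follows_ratio_mean(self):
        up = student_t_test([10, 12, 11], [2, 2.2, 2.1], ratio_mean=5.0)
        assert up.direction is Direction.UP
        down = student_t_test([1, 1.1, 0.9], [10, 11, 12], ratio_mean=0.1)
        assert down.direction is Direction.DOWN


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


class TestAnova:
    def test_identical_groups(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SSB = 6 over dof 2, SSW = 6 over dof 6 -> F = 3; for dof1 = 2 the
        # survival function is (1 + 2F/dof2)^(-dof2/2) = 2^-3 = 0.125
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.f_statistic == pytest.approx(3.0, abs=1e-12)
        assert (res.dof_between, res.dof_within) == (2, 6)
        assert res.p_value == pytest.approx(0.125, abs=1e-9)

    def test_small_groups_excluded(self):
        res = one_way_anova([[1, 2, 3], [5], [2, 3, 4]])
        assert res.dof_between == 1  # the singleton group was dropped

    def test_fewer_than_two_groups_gives_absent_result(self):
        assert one_way_anova([[1, 2, 3]]) is None
        assert one_way_anova([[1, 2, 3], [5]]) is None

    def test_constant_distinct_groups(self):
        res = one_way_anova([[1, 1, 1], [2, 2, 2]])
        assert math.isinf(res.f_statistic)
        assert res.p_value == 0.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_two_group_f_equals_t_squared(self, data):
        values = st.floats(-50, 50, allow_nan=False)
        a = data.draw(st.lists(values, min_size=3, max_size=3))
        b = data.draw(st.lists(values, min_size=3, max_size=3))
        t = student_t_test(a, b)
        f = one_way_anova([a, b])
        if math.isfinite(t.t_statistic) and t.p_value not in (0.0, 1.0):
            assert f.f_statistic == pytest.approx(t.t_statistic**2, rel=1e-9)
            assert f.p_value == pytest.approx(t.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# discordance and rescue
# ---------------------------------------------------------------------------


def _tres(direction, significant=True):
    return TTestResult(
        t_statistic=3.0,
        dof=4,
        p_value=0.01 if significant else 0.5,
        significant=significant,
        direction=direction if significant else Direction.NONE,
    )


class TestDirectionDiscordance:
    def test_same_direction_not_discordant(self):
        results = [_tres(Direction.UP), _tres(Direction.UP), _tres(Direction.NONE, False)]
        assert direction_discordant(results) is False

    def test_opposite_directions_discordant(self):
        assert direction_discordant([_tres(Direction.UP), _tres(Direction.DOWN)]) is True

    def test_nonsignificant_methods_ignored(self):
        results = [_tres(Direction.UP), _tres(Direction.DOWN, significant=False)]
        assert direction_discordant(results) is False


class TestLeaveOneOut:
    def test_outlier_method_identified(self):
        groups = {
            "A": (1.0, 1.1, 0.9),
            "B": (1.05, 0.95, 1.0),
            "C": (3.0, 3.1, 2.9),
        }
        full = one_way_anova(list(groups.values()))
        assert full.p_value < 0.05  # precondition: the full set rejects
        res = leave_one_out_rescue(groups)
        assert res.rescued is True
        assert res.outlier_method == "C"
        # consistency: re-ANOVA without the named outlier accepts
        reduced = one_way_anova([g for m, g in groups.items() if m != "C"])
        assert reduced.p_value > 0.05
        assert res.p_after == pytest.approx(reduced.p_value)

    def test_two_methods_insufficient(self):
        res = leave_one_out_rescue({"A": (1, 1.1, 0.9), "B": (3, 3.1, 2.9)})
        assert res.rescued is False
        assert res.reason == "insufficient methods"

    def test_no_omission_helps(self):
        # three mutually distant tight groups: removing any one leaves two
        # distant groups, so no omission restores homogeneity
        groups = {
            "A": (1.0, 1.01, 0.99),
            "B": (5.0, 5.05, 4.95),
            "C": (9.0, 9.1, 8.9),
        }
        res = leave_one_out_rescue(groups)
        assert res.rescued is False

    def test_tie_broken_by_method_order(self):
        # B and C are symmetric outlier candidates around A
        groups = {
            "A": (1.0, 1.1, 0.9),
            "B": (4.0, 4.1, 3.9),
            "C": (1.02, 1.08, 0.92),
        }
        res = leave_one_out_rescue(groups)
        assert res.rescued
        assert res.outlier_method == "B"
        assert all(p > 0.05 for _m, p in res.candidates)


# ---------------------------------------------------------------------------
# classification + summary
# ---------------------------------------------------------------------------


class TestClassify:
    def test_cascade_categories(self, make_dataset):
        cells = {
            # one method only
            ("hydrophilic", "A", "solo"): {"HT29": [1, 1.1, 0.9], "ASPC1": [1, 1, 1]},
            # three agreeing methods
            ("hydrophilic", "A", "agree"): {"HT29": [2.0, 2.1, 1.9], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "B", "agree"): {"HT29": [2.05, 1.95, 2.0], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "C", "agree"): {"HT29": [1.9, 2.0, 2.1], "ASPC1": [1, 1, 1]},
            # two agreeing + one outlier method
            ("hydrophilic", "A", "outlier"): {"HT29": [1.0, 1.1, 0.9], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "B", "outlier"): {"HT29": [1.05, 0.95, 1.0], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "C", "outlier"): {"HT29": [3.0, 3.1, 2.9], "ASPC1": [1, 1, 1]},
            # two strongly disagreeing methods: unrescuable
            ("hydrophilic", "A", "clash"): {"HT29": [1.0, 1.01, 0.99], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "B", "clash"): {"HT29": [5.0, 5.05, 4.95], "ASPC1": [1, 1, 1]},
        }
        records, summary = classify(make_dataset(cells))
        by_met = {r.metabolite: r for r in records}
        assert by_met["solo"].classification is Classification.SINGLE_METHOD
        assert by_met["agree"].classification is Classification.CONCORDANT
        assert by_met["outlier"].classification is Classification.RESCUED_ONE_OUTLIER
        assert by_met["outlier"].outlier_method == "C"
        assert by_met["clash"].classification is Classification.DISCORDANT
        counts = summary.counts
        assert counts["identified_any"]["hydrophilic"] == 4
        assert counts["multi_method_both"]["hydrophilic"] == 3
        assert counts["anova_concordant"]["hydrophilic"] == 1
        assert counts["concordant_with_rescue"]["hydrophilic"] == 2

    def test_direction_discordance_is_independent_of_category(self, make_dataset):
        cells = {
            ("hydrophilic", "A", "flip"): {"HT29": [4.0, 4.1, 3.9], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "B", "flip"): {"HT29": [0.25, 0.26, 0.24], "ASPC1": [1, 1, 1]},
            ("hydrophilic", "C", "flip"): {"HT29": [1.0, 1.05, 0.95], "ASPC1": [1, 1, 1]},
        }
        records, summary = classify(make_dataset(cells))
        rec = records[0]
        assert rec.direction_discordant is True
        assert summary.counts["direction_discordant"]["hydrophilic"] == 1

    def test_empty_dataset_all_zero(self, make_dataset):
        _records, summary = classify(make_dataset({}))
        for row in summary.counts.values():
            assert row == {"hydrophilic": 0, "hydrophobic": 0, "total": 0}

    def test_scale_invariance_per_method(self, make_dataset):
        rng = np.random.default_rng(11)
        cells = {}
        for met in [f"m{i}" for i in range(8)]:
            for method in "ABC":
                cells[("hydrophilic", method, met)] = {
                    "HT29": list(rng.lognormal(1, 0.3, 3)),
                    "ASPC1": list(rng.lognormal(1, 0.3, 3)),
                }
        base_records, base_summary = classify(make_dataset(cells))

        scaled = {
            key: {
                s: [v * (1e4 if key[1] == "B" else 1.0) for v in vals]
                for s, vals in samples.items()
            }
            for key, samples in cells.items()
        }
        records, summary = classify(make_dataset(scaled))
        assert summary.counts == base_summary.counts
        for rec, base in zip(records, base_records):
            assert rec.classification is base.classification
            for m, rs in rec.ratio_sets.items():
                assert rs.ratios == pytest.approx(base.ratio_sets[m].ratios)

    def test_count_cascade_invariants(self, make_dataset):
        rng = np.random.default_rng(23)
        cells = {}
        for i in range(25):
            met = f"m{i}"
            effect = rng.choice([1.0, 2.0, 0.5])
            for method in "ABCD":
                if rng.random() < 0.7:
                    bias = 3.0 if (method == "D" and rng.random() < 0.3) else 1.0
                    cells[("hydrophilic", method, met)] = {
                        "HT29": list(effect * bias * rng.lognormal(2, 0.08, 3)),
                        "ASPC1": list(rng.lognormal(2, 0.08, 3)),
                    }
        _records, summary = classify(make_dataset(cells))
        c = summary.counts
        for col in ("hydrophilic", "hydrophobic", "total"):
            assert c["direction_discordant"][col] <= c["t_significant_multi"][col]
            assert c["t_significant_multi"][col] <= c["multi_method_both"][col]
            assert c["multi_method_both"][col] <= c["identified_any"][col]
            assert c["anova_concordant"][col] <= c["concordant_with_rescue"][col]
            assert c["concordant_with_rescue"][col] <= c["multi_method_both"][col]


class TestSummaryTable:
    def test_rounding_half_away_from_zero(self):
        assert round_half_away(54.85, 1) == 54.9
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(39.26, 1) == 39.3

    def test_aggregation_of_category_counts(self):
        table = SummaryTable.from_category_counts(
            [206, 148, 104, 5, 57, 98], [584, 285, 199, 7, 113, 162]
        )
        assert table.counts["identified_any"]["total"] == 790
        assert table.counts["multi_method_both"]["total"] == 433
        assert table.percentages["multi_method_pct"]["total"] == 54.8
        assert table.percentages["concordant_with_rescue_pct"]["total"] == 60.0

    def test_zero_denominators_give_zero_percent(self):
        table = SummaryTable.from_category_counts([0] * 6, [0] * 6)
        for pct in table.percentages.values():
            assert pct == {"hydrophilic": 0.0, "hydrophobic": 0.0, "total": 0.0}
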