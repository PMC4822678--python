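"""2x2 statistics against independent enumeration oracles and published values."""

import math
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hnf1b_score import (
    Cohort,
    CohortValidationError,
    DegenerateTableError,
    MutationStatus,
    PatientRecord,
    TwoByTwoTable,
    exact_or_ci,
    feature_table,
    fisher_exact,
    format_or,
    mann_whitney,
    odds_ratio,
    woolf_ci,
)
from hnf1b_score.association_stats import association_report
from hnf1b_score.phenotype_model import KidneyFindings
from hnf1b_score.score_engine import score_cohort
from hnf1b_score.synthetic_cohort import CohortConfig, generate_cohort

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _hypergeom_pmf(x, r1, r2, c1):
    return comb(r1, x) * comb(r2, c1 - x) / comb(r1 + r2, c1)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    return sum(p for x in xs if (p := _hypergeom_pmf(x, r1, r2, c1)) <= p_obs * (1 + 1e-9))


def _nchg_tail(a, r1, r2, c1, psi, upper):
    """Noncentral hypergeometric tail, written independently of scipy."""
    xs = list(range(max(0, c1 - r2), min(r1, c1) + 1))
    w = [comb(r1, x) * comb(r2, c1 - x) * psi**x for x in xs]
    total = sum(w)
    if upper:  # P(X <= a)
        return sum(wi for x, wi in zip(xs, w) if x <= a) / total
    return sum(wi for x, wi in zip(xs, w) if x >= a) / total


def exact_ci_oracle(a, b, c, d, alpha=0.025):
    """Conditional-exact limits by bisection on the tail probabilities."""
    r1, r2, c1 = a + b, c + d, a + c

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    x_min, x_max = max(0, c1 - r2), min(r1, c1)
    low = 0.0 if a == x_min else bisect(
        lambda psi: alpha - _nchg_tail(a, r1, r2, c1, psi, upper=False), 1e-12, 1e12
    )
    high = math.inf if a == x_max else bisect(
        lambda psi: _nchg_tail(a, r1, r2, c1, psi, upper=True) - alpha, 1e-12, 1e12
    )
    return low, high


# ---------------------------------------------------------------------------
# odds ratio and CIs
# ---------------------------------------------------------------------------


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((54, 123, 83, 426), 2.25),  # antenatal abnormalities, whole cohort
            ((15, 46, 8, 201), 8.19),  # hypoplasia, adults
            ((10, 10, 10, 10), 1.0),
        ],
    )
    def test_cross_product_values(self, cells, expected):
        assert odds_ratio(TwoByTwoTable(*cells)) == pytest.approx(expected, abs=0.005)

    def test_zero_and_infinite_conventions(self):
        assert odds_ratio(TwoByTwoTable(0, 5, 3, 7)) == 0.0
        assert odds_ratio(TwoByTwoTable(5, 0, 3, 7)) == math.inf
        assert math.isnan(odds_ratio(TwoByTwoTable(0, 5, 0, 7)))

    def test_all_zero_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            TwoByTwoTable(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(1, 50)] * 4))
    @settings(max_examples=100, derandomize=True)
    def test_swap_symmetries(self, cells):
        a, b, c, d = cells
        orig = odds_ratio(TwoByTwoTable(a, b, c, d))
        both_swapped = odds_ratio(TwoByTwoTable(d, c, b, a))
        row_swapped = odds_ratio(TwoByTwoTable(c, d, a, b))
        assert orig == pytest.approx(both_swapped, rel=1e-12)
        assert orig == pytest.approx(1 / row_swapped, rel=1e-12)


class TestWoolfCi:
    @pytest.mark.parametrize(
        "cells,lo,hi",
        [
            ((54, 123, 83, 426), 1.5, 3.4),  # antenatal, whole cohort
            ((15, 162, 5, 504), 3.3, 26.1),  # liver tests, whole cohort
        ],
    )
    def test_published_intervals(self, cells, lo, hi):
        low, high = woolf_ci(TwoByTwoTable(*cells))
        assert round(low, 1) == lo
        assert round(high, 1) == hi

    def test_balanced_table_symmetric_on_log_scale(self):
        low, high = woolf_ci(TwoByTwoTable(10, 10, 10, 10))
        assert math.log(low) == pytest.approx(-math.log(high), abs=1e-12)

    def test_zero_cell_refused(self):
        with pytest.raises(DegenerateTableError):
            woolf_ci(TwoByTwoTable(0, 5, 3, 7))

    @pytest.mark.parametrize("factor", [2, 5, 10])
    def test_width_shrinks_as_cells_scale_up(self, factor):
        base = TwoByTwoTable(8, 15, 11, 30)
        lo1, hi1 = woolf_ci(base)
        lo2, hi2 = woolf_ci(TwoByTwoTable(8 * factor, 15 * factor, 11 * factor, 30 * factor))
        assert math.log(hi2) - math.log(lo2) < math.log(hi1) - math.log(lo1)


class TestExactOrCi:
    def test_lower_limit_zero_when_a_zero(self):
        low, high = exact_or_ci(TwoByTwoTable(0, 61, 1, 208))
        assert low == 0.0
        assert math.isfinite(high)

    def test_toy_table_matches_inversion_oracle(self):
        got = exact_or_ci(TwoByTwoTable(0, 5, 2, 8))
        want = exact_ci_oracle(0, 5, 2, 8)
        assert got[0] == want[0] == 0.0
        assert got[1] == pytest.approx(want[1], rel=1e-6)

    @pytest.mark.parametrize("cells", [(3, 9, 2, 14), (1, 5, 4, 6), (7, 3, 2, 11)])
    def test_all_positive_table_matches_oracle_and_contains_or(self, cells):
        got = exact_or_ci(TwoByTwoTable(*cells))
        want = exact_ci_oracle(*cells)
        assert got[0] == pytest.approx(want[0], rel=1e-5)
        assert got[1] == pytest.approx(want[1], rel=1e-5)
        assert got[0] <= odds_ratio(TwoByTwoTable(*cells)) <= got[1]

    def test_midp_limits_reproduce_published_zero_cell_bounds(self):
        # multicystic/dysplastic kidney in adults: published 0 (0-65.1)
        low, high = exact_or_ci(TwoByTwoTable(0, 61, 1, 208), midp=True)
        assert low == 0.0
        assert round(high, 1) == 65.1
        # liver test abnormalities in children: published 0 (0-9.0)
        low, high = exact_or_ci(TwoByTwoTable(0, 116, 2, 298), midp=True)
        assert round(high, 1) == 9.0

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            exact_or_ci(TwoByTwoTable(0, 0, 3, 7))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact(TwoByTwoTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_hyperechogenicity_whole_cohort_p(self):
        # published as p = 0.0002
        p = fisher_exact(TwoByTwoTable(23, 154, 22, 487))
        assert round(p, 4) == 0.0002

    def test_degenerate_margin_p_one(self):
        assert fisher_exact(TwoByTwoTable(0, 0, 3, 7)) == 1.0

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(max_examples=300, derandomize=True)
    def test_matches_enumeration_oracle_small_tables(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0 or a + b + c + d > 20:
            return
        t = TwoByTwoTable(a, b, c, d)
        if t.degenerate_margin():
            return
        assert fisher_exact(t) == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u_statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_small_samples_exact(self):
        # 2 of the 20 equally likely rank assignments are as extreme
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.median_x == 2.0 and res.median_y == 5.0

    def test_empty_sample_rejected(self):
        with pytest.raises(CohortValidationError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_generated_carrier_scores_shift_detected(self, seed):
        """Carrier vs non-carrier score distributions separate at study size."""
        cohort = generate_cohort(CohortConfig(seed=seed))
        score_cohort(cohort)
        carriers = [r.raw_score for r in cohort if r.mutation_status is MutationStatus.MUTATION]
        others = [r.raw_score for r in cohort if r.mutation_status is MutationStatus.NORMAL]
        assert mann_whitney(carriers, others).p_value < 1e-4


class TestFeatureTable:
    def test_two_record_cohort(self):
        case = PatientRecord(patient_id="A", mutation_status=MutationStatus.MUTATION,
                             hypomagnesaemia=True)
        ctrl = PatientRecord(patient_id="B", mutation_status=MutationStatus.NORMAL)
        t = feature_table(Cohort(records=[case, ctrl]), "hypomagnesaemia")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_renal_feature_present_on_either_kidney(self):
        recs = [
            PatientRecord(patient_id="A", mutation_status=MutationStatus.MUTATION,
                          kidney_right=KidneyFindings(cysts=True)),
            PatientRecord(patient_id="B", mutation_status=MutationStatus.NORMAL),
        ]
        t = feature_table(Cohort(records=recs), "renal_cysts")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_unknown_status_excluded(self):
        recs = [
            PatientRecord(patient_id="A", mutation_status=MutationStatus.MUTATION),
            PatientRecord(patient_id="B", mutation_status=MutationStatus.UNKNOWN),
            PatientRecord(patient_id="C", mutation_status=MutationStatus.NORMAL),
        ]
        t = feature_table(Cohort(records=recs), "family_history")
        assert t.n == 2

    def test_empty_subgroup_rejected(self):
        recs = [PatientRecord(patient_id="A", mutation_status=MutationStatus.UNKNOWN)]
        with pytest.raises(CohortValidationError):
            feature_table(Cohort(records=recs), "family_history")

    def test_subgroup_counts_consistent(self, synthetic_cohort):
        t_all = feature_table(synthetic_cohort, "renal_cysts", "all")
        t_child = feature_table(synthetic_cohort, "renal_cysts", "child")
        t_adult = feature_table(synthetic_cohort, "renal_cysts", "adult")
        assert t_all.a == t_child.a + t_adult.a
        assert t_all.n == t_child.n + t_adult.n


class TestReporting:
    @pytest.mark.parametrize(
        "value,expected", [(2.2534, "2.3"), (169.2, "169"), (math.inf, "inf"), (0.04, "0.0")]
    )
    def test_format_or(self, value, expected):
        assert format_or(value) == expected

    def test_association_report_shape(self, synthetic_cohort):
        frame = association_report(synthetic_cohort, "all")
        assert len(frame) == 15
        assert {"feature", "p_value", "odds_ratio", "ci_low", "ci_high"} <= set(frame.columns)
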