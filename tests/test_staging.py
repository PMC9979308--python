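"""Contingency-table staging metrics against hand-computed values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dictmri import staging


@pytest.fixture(scope="module")
def mr_table():
    return staging.bundled_table("mr_cohort")


@pytest.fixture(scope="module")
def ct_table():
    return staging.bundled_table("ct_cohort")


class TestBundledCohorts:
    def test_mr_margins_and_size(self, mr_table):
        assert mr_table.n == 146
        assert mr_table.imaging_totals.tolist() == [55, 56, 35]
        assert mr_table.pathology_totals.tolist() == [41, 58, 47]

    def test_ct_margins_and_size(self, ct_table):
        assert ct_table.n == 98
        assert ct_table.imaging_totals.tolist() == [41, 34, 23]
        assert ct_table.pathology_totals.tolist() == [36, 37, 25]

    def test_mr_sensitivities(self, mr_table):
        # 19/41, 18/58, 15/47
        expected = [46.34, 31.03, 31.91]
        got = [round(100 * staging.sensitivity(mr_table, k), 2) for k in range(3)]
        assert got == expected

    def test_mr_specificity_standard_definition(self, mr_table):
        # one-vs-rest from the raw counts: (105-36)/105 for stage 0
        assert staging.specificity(mr_table, 0) == pytest.approx(69 / 105)

    def test_mr_trace_coincidence(self, mr_table):
        assert staging.coincidence_rate(mr_table) == pytest.approx(52 / 146)

    def test_demographics_rows_sum_to_cohort(self):
        demo = staging.bundled_demographics()
        totals = demo.sum(axis=1)
        assert totals.tolist() == [41, 58, 47]
        assert int(totals.sum()) == 146


class TestMetricDefinitions:
    def test_diagonal_table_maximal(self):
        t = staging.StagingTable(np.diag([5, 7, 9]), ("a", "b", "c"))
        assert staging.coincidence_rate(t) == 1.0
        assert staging.agreement_kappa(t) == pytest.approx(1.0)
        for k in range(3):
            assert staging.sensitivity(t, k) == 1.0
            assert staging.specificity(t, k) == 1.0

    def test_uniform_table(self):
        t = staging.StagingTable(np.full((3, 3), 4), ("a", "b", "c"))
        assert staging.coincidence_rate(t) == pytest.approx(1 / 3)
        for k in range(3):
            assert staging.specificity(t, k) == pytest.approx(2 / 3)
        assert staging.agreement_kappa(t) == pytest.approx(0.0)

    def test_chi_square_closed_form(self):
        t = staging.StagingTable([[10, 0], [0, 10]], ("a", "b"))
        chi2, p = staging.chi_square_test(t)
        assert chi2 == pytest.approx(20.0)
        t_indep = staging.StagingTable([[4, 8], [2, 4]], ("a", "b"))
        chi2, p = staging.chi_square_test(t_indep)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi_square_permutation_invariance(self, mr_table):
        chi2, _ = staging.chi_square_test(mr_table)
        perm = [2, 0, 1]
        counts = mr_table.counts[np.ix_(perm, perm)]
        t2 = staging.StagingTable(counts, tuple(mr_table.labels[i] for i in perm))
        chi2p, _ = staging.chi_square_test(t2)
        assert chi2 == pytest.approx(chi2p)

    def test_kappa_hand_example(self):
        t = staging.StagingTable([[45, 5], [5, 45]], ("a", "b"))
        assert staging.agreement_kappa(t) == pytest.approx(0.8)

    def test_metrics_invariant_under_relabeling(self, mr_table):
        perm = [1, 2, 0]
        t2 = staging.StagingTable(
            mr_table.counts[np.ix_(perm, perm)], tuple(mr_table.labels[i] for i in perm)
        )
        for new_k, old_k in enumerate(perm):
            assert staging.sensitivity(t2, new_k) == pytest.approx(
                staging.sensitivity(mr_table, old_k)
            )
        assert staging.agreement_kappa(t2) == pytest.approx(
            staging.agreement_kappa(mr_table)
        )


@st.composite
def tables(draw):
    k = draw(st.integers(2, 4))
    cells = draw(
        st.lists(st.integers(0, 30), min_size=k * k, max_size=k * k).filter(
            lambda c: sum(c) > 0
        )
    )
    return staging.StagingTable(
        np.array(cells).reshape(k, k), tuple(f"s{i}" for i in range(k))
    )


class TestAlgebraicProperties:
    @given(tables())
    @settings(max_examples=50, deadline=None)
    def test_coincidence_is_margin_weighted_recall(self, t):
        cols = t.pathology_totals
        recalls = [
            staging.sensitivity(t, k) if cols[k] > 0 else 0.0 for k in range(t.k)
        ]
        weighted = sum(r * c for r, c in zip(recalls, cols)) / t.n
        assert staging.coincidence_rate(t) == pytest.approx(weighted)

    @given(tables())
    @settings(max_examples=50, deadline=None)
    def test_kappa_bounded_by_observed_agreement(self, t):
        kappa = staging.agreement_kappa(t)
        if not np.isnan(kappa):
            assert kappa <= staging.coincidence_rate(t) + 1e-12


class TestReport:
    def test_report_percentages_rounded_half_up(self, mr_table):
        _, report = staging.evaluate_cohort(mr_table)
        assert report["sensitivity_pct"].tolist() == [46.34, 31.03, 31.91]
        assert report["sensitivity_fraction"].tolist() == ["19/41", "18/58", "15/47"]

    def test_identity_table_report(self):
        t = staging.StagingTable(np.diag([10, 10, 10]), ("a", "b", "c"))
        m, report = staging.evaluate_cohort(t)
        assert all(report["sensitivity_pct"] == 100.0)
        assert all(report["specificity_pct"] == 100.0)
        assert m.agreement_kappa == pytest.approx(1.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            staging.StagingTable(np.ones((2, 3)), ("a", "b"))
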