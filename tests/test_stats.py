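import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neodose as nd
from neodose.stats import (
    DegenerateTableError,
    UndefinedRateRatioError,
    summarize_per_patient,
)


def small_lines(rows):
    """lines/classifications pair from (line_id, order_id, patient, day, drug, erroneous)."""
    lines = pd.DataFrame(
        [
            {"ordered_medication_id": lid, "order_id": oid, "patient_id": pid,
             "day": day, "drug": drug}
            for lid, oid, pid, day, drug, _ in rows
        ]
    )
    cls = pd.DataFrame(
        [
            {"ordered_medication_id": lid,
             "interception": "nonintercepted" if err else "no_error"}
            for lid, *_, err in rows
        ]
    )
    return cls, lines


class TestCountUnits:
    def test_one_erroneous_line_in_two_orders(self):
        cls, lines = small_lines(
            [("L1", "O1", "P1", 0, "ampicillin", True),
             ("L2", "O2", "P1", 0, "gentamicin", False)]
        )
        pd_counts = nd.count_units(cls, lines, "patient_day")
        order_counts = nd.count_units(cls, lines, "order")
        assert (pd_counts.erroneous, pd_counts.total) == (1, 1)
        assert (order_counts.erroneous, order_counts.total) == (1, 2)

    def test_same_drug_twice_one_day_is_one_medication_day(self):
        cls, lines = small_lines(
            [("L1", "O1", "P1", 0, "ampicillin", True),
             ("L2", "O2", "P1", 0, "ampicillin", True)]
        )
        md = nd.count_units(cls, lines, "medication_day")
        om = nd.count_units(cls, lines, "ordered_medication")
        assert (md.erroneous, md.total) == (1, 1)
        assert (om.erroneous, om.total) == (2, 2)

    def test_unknown_unit_rejected(self):
        cls, lines = small_lines([("L1", "O1", "P1", 0, "ampicillin", False)])
        with pytest.raises(ValueError):
            nd.count_units(cls, lines, "medication-week")

    def test_coarsening_bounds_on_simulated_data(
        self, poe_dataset, poe_classified, noe_dataset, noe_classified
    ):
        """Erroneous patient-days <= orders <= ordered medications;
        medication-days <= ordered medications."""
        for ds, cls in ((poe_dataset, poe_classified), (noe_dataset, noe_classified)):
            counts = {
                u: nd.count_units(cls, ds.lines, u).erroneous for u in nd.stats.UNITS
            }
            assert counts["patient_day"] <= counts["order"] <= counts["ordered_medication"]
            assert counts["medication_day"] <= counts["ordered_medication"]


class TestRateRatio:
    def test_published_count_examples(self):
        assert round(nd.rate_ratio(301, 2357, 175, 2297), 2) == 0.60
        assert round(nd.rate_ratio(147, 601, 97, 648), 2) == 0.61

    def test_equal_rates_give_unity(self):
        assert nd.rate_ratio(10, 100, 30, 300) == pytest.approx(1.0)

    def test_zero_reference_errors_is_undefined(self):
        with pytest.raises(UndefinedRateRatioError):
            nd.rate_ratio(0, 100, 5, 100)


class TestPearsonChi2:
    def test_brute_force_example(self):
        # n(ad-bc)^2 / product of margins, evaluated directly
        a, b, c, d = 16, 49, 5, 62
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, p = nd.pearson_chi2_2x2(a, b, c, d)
        assert chi2 == pytest.approx(expected)
        assert chi2 == pytest.approx(7.26, abs=0.01)
        assert p < 0.01

    def test_independent_table_is_zero(self):
        chi2, p = nd.pearson_chi2_2x2(10, 10, 10, 10)
        assert chi2 == 0
        assert p == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_row_swap_symmetry(self, table):
        a, b, c, d = table
        assert nd.pearson_chi2_2x2(a, b, c, d)[0] == pytest.approx(
            nd.pearson_chi2_2x2(c, d, a, b)[0]
        )

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            nd.pearson_chi2_2x2(0, 0, 5, 5)


class TestMiettinenCI:
    def test_always_brackets_the_ratio(self):
        low, high = nd.miettinen_ci(0.6, 10.0)
        assert low <= 0.6 <= high

    def test_widens_as_chi2_decreases(self):
        narrow = nd.miettinen_ci(0.6, 40.0)
        wide = nd.miettinen_ci(0.6, 10.0)
        assert wide[0] < narrow[0] and wide[1] > narrow[1]

    def test_large_chi2_limit_collapses_to_rr(self):
        low, high = nd.miettinen_ci(0.6, 1e10)
        assert low == pytest.approx(0.6, rel=1e-3)
        assert high == pytest.approx(0.6, rel=1e-3)

    def test_zero_chi2_undefined(self):
        with pytest.raises(DegenerateTableError):
            nd.miettinen_ci(1.0, 0.0)


class TestMantelTrend:
    def test_identical_distributions_give_zero(self):
        chi2, p = nd.mantel_trend_chi2([[30, 20, 10], [30, 20, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_two_categories_reduce_to_pearson(self, table):
        """Algebraic identity: the score-form trend statistic on a 2x2
        equals the uncorrected Pearson chi-square."""
        a, b, c, d = table
        trend, _ = nd.mantel_trend_chi2([[a, b], [c, d]])
        pearson, _ = nd.pearson_chi2_2x2(a, b, c, d)
        assert trend == pytest.approx(pearson)

    def test_shifted_distribution_detected(self):
        chi2, p = nd.mantel_trend_chi2([[40, 20, 5], [5, 20, 40]])
        assert chi2 > 0
        assert p < 0.001

    def test_corrected_variant_scales_by_n_minus_one(self):
        table = [[16, 49], [5, 62]]
        plain, _ = nd.mantel_trend_chi2(table)
        corrected, _ = nd.mantel_trend_chi2(table, corrected=True)
        n = sum(sum(r) for r in table)
        assert corrected == pytest.approx(plain * (n - 1) / n)

    def test_empty_group_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            nd.mantel_trend_chi2([[0, 0], [5, 5]])


def permutation_p_oracle(a, b):
    """Exhaustive two-sided permutation p for the U statistic, enumerating
    every labelling of the pooled values (independent brute force)."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)
    mu = na * (n - na) / 2

    def u_of(indices):
        chosen = [pooled[i] for i in indices]
        rest = [pooled[i] for i in range(n) if i not in indices]
        u = 0.0
        for x in chosen:
            for y in rest:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = abs(u_of(tuple(range(na))) - mu)
    hits = total = 0
    for indices in itertools.combinations(range(n), na):
        total += 1
        if abs(u_of(indices) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        u, p = nd.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation_gives_zero_u(self):
        u, p = nd.mann_whitney([0, 0, 0], [5, 5, 5])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=0.01)  # 2/C(6,3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 5), min_size=2, max_size=4),
        b=st.lists(st.integers(0, 5), min_size=2, max_size=4),
    )
    def test_exact_p_matches_permutation_enumeration(self, a, b):
        _, p = nd.mann_whitney(a, b)
        assert p == pytest.approx(permutation_p_oracle(a, b))

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 6, size=60)
        b = rng.integers(1, 7, size=60)
        _, p = nd.mann_whitney(a, b)
        assert 0 < p < 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nd.mann_whitney([], [1])


class TestPerPatientSummary:
    def test_hand_example(self):
        s = summarize_per_patient([0, 0, 2, 4])
        assert s.median == 1
        assert s.fraction_error_free == 0.5

    def test_all_zero(self):
        s = summarize_per_patient([0, 0, 0])
        assert s.median == 0
        assert s.fraction_error_free == 1.0

    def test_error_free_patients_counted_from_patient_table(
        self, poe_dataset, poe_classified
    ):
        s = nd.per_patient_summary(poe_classified, poe_dataset.lines, poe_dataset.patients)
        assert s.n_patients == len(poe_dataset.patients)
        assert 0 <= s.fraction_error_free <= 1
        assert s.q25 <= s.median <= s.q75


class TestComplianceRate:
    @pytest.mark.parametrize(
        "complied, ignored, expected_pct",
        [(232, 107, 68), (136, 176, 44), (0, 10, 0)],
    )
    def test_published_compliance_fractions(self, complied, ignored, expected_pct):
        responses = ["complied"] * complied + ["ignored"] * ignored
        assert round(100 * nd.compliance_rate(responses)) == expected_pct

    def test_pending_only_is_undefined(self):
        with pytest.raises(ValueError):
            nd.compliance_rate(["pending", "pending"])
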