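import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from chemovote.association import (
    build_association_table,
    coefficient_se,
    correlation_coefficient,
    difference_of_means_test,
    partition_terpenes,
)
from chemovote.datasets import PUBLISHED_SUMMARY
from chemovote.models import (
    INSUFFICIENT_DATA,
    NA_ZERO_BOTH,
    VALID,
    AnalyteStats,
    VoteTally,
    WeightedProfile,
)

# physically meaningful % w/w magnitudes: exact zero (below detection) or a
# quantifiable concentration — avoids float-underflow regimes where a + b
# cannot distinguish the two operands
concentrations = st.one_of(st.just(0.0), st.floats(1e-4, 30))


class TestCoefficient:
    @pytest.mark.parametrize(
        "wa_me, wa_le, expected",
        [
            (18.01, 13.67, 0.137),  # THC-dominant enrichment in the preferred group
            (0.075, 2.62, -0.944),  # CBD enriched in the disfavoured group
            (1.850, 1.621, 0.066),  # total terpenes, near balance
            (0.0, 0.069, -1.000),  # present only in the disfavoured group
            (0.013, 0.0, 1.000),  # present only in the preferred group
            (5.5, 5.5, 0.0),  # exact balance
        ],
    )
    def test_worked_examples_at_three_decimals(self, wa_me, wa_le, expected):
        assert round(correlation_coefficient(wa_me, wa_le), 3) == expected

    def test_absent_from_both_groups_is_na(self):
        assert correlation_coefficient(0.0, 0.0) is None

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_coefficient(-0.1, 0.2)

    @settings(max_examples=300, derandomize=True)
    @given(concentrations, concentrations)
    def test_antisymmetry_range_and_boundary(self, a, b):
        cc = correlation_coefficient(a, b)
        if a == 0 and b == 0:
            assert cc is None
            return
        assert -1.0 <= cc <= 1.0
        assert cc == pytest.approx(-correlation_coefficient(b, a), abs=1e-12)
        # ±1 exactly when one side is absent
        assert (cc == 1.0) == (b == 0 < a)
        assert (cc == -1.0) == (a == 0 < b)

    @settings(max_examples=200, derandomize=True)
    @given(concentrations, concentrations, st.floats(0.01, 100))
    def test_scale_invariance(self, a, b, lam):
        if a + b == 0:
            return
        assert correlation_coefficient(lam * a, lam * b) == pytest.approx(
            correlation_coefficient(a, b), rel=1e-9, abs=1e-12
        )


class TestPublishedCoefficients:
    """The published association table as an oracle for the coefficient.

    Self-consistent rows (printed averages reproduce the printed coefficient
    at 3 decimals) must match exactly. The remaining printed coefficients
    were computed from unrounded lab data, so the check there is that the
    printed value lies within the exact interval of coefficients attainable
    from operands consistent with the printed rounding.
    """

    EXACT_ROWS = {
        "Δ9-Tetrahydrocannabinol": 0.137,
        "Cannabidiol": -0.944,
        "Total terpenes": 0.066,
        "Guaiol": -1.000,
        "α-Phellandrene": -1.000,
        "3-Carene": -1.000,
        "γ-Terpineol": 1.000,
        "Valencene": 1.000,
    }
    NA_ROWS = {"Geraniol", "Nerol", "Cedrol"}

    def test_self_consistent_rows_reproduce_exactly(self):
        by_name = {r.analyte: r for r in PUBLISHED_SUMMARY}
        for analyte, expected in self.EXACT_ROWS.items():
            row = by_name[analyte]
            cc = correlation_coefficient(row.wa_me_value, row.wa_le_value)
            assert round(cc, 3) == expected, analyte

    def test_absent_constituents_reported_na(self):
        by_name = {r.analyte: r for r in PUBLISHED_SUMMARY}
        for analyte in self.NA_ROWS:
            row = by_name[analyte]
            assert correlation_coefficient(row.wa_me_value, row.wa_le_value) is None

    @pytest.mark.parametrize(
        "row", [r for r in PUBLISHED_SUMMARY if r.cc_printed is not None],
        ids=lambda r: r.analyte,
    )
    def test_every_printed_coefficient_consistent_with_printed_rounding(self, row):
        half_me, half_le = row.rounding_half_widths()
        a_lo = max(row.wa_me_value - half_me, 0.0)
        a_hi = row.wa_me_value + half_me
        b_lo = max(row.wa_le_value - half_le, 0.0)
        b_hi = row.wa_le_value + half_le
        # cc is increasing in a and decreasing in b
        cc_lo = correlation_coefficient(a_lo, b_hi)
        cc_hi = correlation_coefficient(a_hi, b_lo)
        assert cc_lo - 5e-4 <= row.cc_printed <= cc_hi + 5e-4, row.analyte


class TestDifferenceOfMeansTest:
    def test_identical_summaries_give_null_identity(self):
        t, df, p, degenerate = difference_of_means_test(5.0, 1.2, 12, 5.0, 1.2, 12)
        assert (t, p, degenerate) == (0.0, 1.0, False)

    def test_group_swap_negates_t_and_preserves_p(self):
        a = difference_of_means_test(5.0, 1.0, 12, 4.0, 2.0, 9)
        b = difference_of_means_test(4.0, 2.0, 9, 5.0, 1.0, 12)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.df == pytest.approx(b.df)

    def test_equal_variance_case_matches_direct_welch_formula(self):
        t, df, p, _ = difference_of_means_test(5.0, 1.0, 12, 4.0, 1.0, 12)
        assert t == pytest.approx(2.4495, abs=1e-4)
        assert df == pytest.approx(22.0)
        assert p == pytest.approx(0.0227, abs=2e-4)

    def test_matches_scipy_from_summary_stats(self):
        res = difference_of_means_test(3.2, 1.1, 12, 2.5, 0.4, 10)
        ref = sps.ttest_ind_from_stats(3.2, 1.1, 12, 2.5, 0.4, 10, equal_var=False)
        assert res.t_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_variances(self):
        equal = difference_of_means_test(2.0, 0.0, 12, 2.0, 0.0, 12)
        assert (equal.t_stat, equal.p_value, equal.degenerate) == (0.0, 1.0, False)
        unequal = difference_of_means_test(2.0, 0.0, 12, 3.0, 0.0, 12)
        assert unequal.p_value == 0.0 and unequal.degenerate

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            difference_of_means_test(1.0, 0.5, 1, 2.0, 0.5, 12)


def make_profile(group, entries, n=12, absent=()):
    """Profile from {analyte: (mean, sd)} with uniform n."""
    stats = {
        analyte: AnalyteStats(
            weighted_mean=m, weighted_sd=s, weighted_se=s / math.sqrt(n), n_measurements=n
        )
        for analyte, (m, s) in entries.items()
    }
    return WeightedProfile(
        group=group,
        strains=("A", "B", "C", "D"),
        strain_votes={"A": 44, "B": 39, "C": 36, "D": 33},
        stats=stats,
        absent=frozenset(absent),
    )


class TestAssociationTable:
    ENTRIES_ME = {
        "Δ9-Tetrahydrocannabinol": (18.01, 2.0),
        "Myrcene": (0.319, 0.10),
        "Guaiol": (0.0, 0.0),
        "Geraniol": (0.0, 0.0),
        "Total terpenes": (1.850, 0.4),
    }
    ENTRIES_LE = {
        "Δ9-Tetrahydrocannabinol": (13.67, 2.0),
        "Myrcene": (0.357, 0.12),
        "Guaiol": (0.069, 0.03),
        "Geraniol": (0.0, 0.0),
        "Total terpenes": (1.621, 0.4),
    }

    def table(self, **kwargs):
        return build_association_table(
            make_profile("most_effective", self.ENTRIES_ME),
            make_profile("least_effective", self.ENTRIES_LE),
            **kwargs,
        )

    def test_rows_in_panel_order_with_expected_statuses(self):
        table = self.table()
        assert [r.analyte for r in table] == [
            "Δ9-Tetrahydrocannabinol",
            "Total terpenes",
            "Myrcene",
            "Geraniol",
            "Guaiol",
        ]
        by_name = {r.analyte: r for r in table}
        assert by_name["Geraniol"].status == NA_ZERO_BOTH
        assert by_name["Geraniol"].cc is None and by_name["Geraniol"].p_value is None
        assert by_name["Guaiol"].status == VALID
        assert by_name["Guaiol"].cc == -1.0
        assert round(by_name["Total terpenes"].cc, 3) == 0.066

    def test_flags_follow_alpha_and_marginal_band(self):
        by_name = {r.analyte: r for r in self.table(alpha=0.05, marginal_band=0.10)}
        for row in by_name.values():
            if row.status != VALID:
                assert row.flag == ""
            elif row.p_value < 0.05:
                assert row.flag == "significant"
            elif row.p_value < 0.10:
                assert row.flag == "marginal"
            else:
                assert row.flag == ""

    def test_alpha_zero_flags_nothing_significant(self):
        table = self.table(alpha=0.0, marginal_band=0.10)
        assert all(r.flag != "significant" for r in table)

    def test_bh_column_is_monotone_and_bounded(self):
        rows = [r for r in self.table() if r.status == VALID]
        rows.sort(key=lambda r: r.p_value)
        qs = [r.q_value for r in rows]
        assert all(q == pytest.approx(min(q, 1.0)) for q in qs)
        assert qs == sorted(qs)
        assert all(q >= p for q, p in zip(qs, (r.p_value for r in rows)))

    def test_panel_mismatch_names_offenders(self):
        me = make_profile("most_effective", self.ENTRIES_ME)
        le = make_profile(
            "least_effective",
            {**self.ENTRIES_LE, "Linalool": (0.1, 0.01)},
        )
        with pytest.raises(ValueError, match="Linalool"):
            build_association_table(me, le)

    def test_absent_analyte_reported_insufficient(self):
        me = make_profile("most_effective", self.ENTRIES_ME, absent={"Cedrol"})
        le = make_profile(
            "least_effective", {**self.ENTRIES_LE, "Cedrol": (0.01, 0.001)}
        )
        by_name = {r.analyte: r for r in build_association_table(me, le)}
        assert by_name["Cedrol"].status == INSUFFICIENT_DATA

    def test_coefficient_se_shrinks_with_group_se(self):
        wide = coefficient_se(0.4, 0.1, 0.2, 0.1)
        narrow = coefficient_se(0.4, 0.01, 0.2, 0.01)
        assert narrow < wide


class TestPartition:
    def test_published_examples_partition_at_half_a_milligram_per_gram(self):
        table = build_association_table(
            make_profile(
                "most_effective",
                {
                    "trans-Nerolidol": (0.444, 0.1),
                    "Eucalyptol": (0.0, 0.0),
                    "Cannabidiol": (0.075, 0.01),
                    "Total terpenes": (1.850, 0.3),
                },
            ),
            make_profile(
                "least_effective",
                {
                    "trans-Nerolidol": (0.146, 0.05),
                    "Eucalyptol": (0.005, 0.002),
                    "Cannabidiol": (2.62, 0.4),
                    "Total terpenes": (1.621, 0.3),
                },
            ),
        )
        part = partition_terpenes(table, threshold=0.05)
        assert "trans-Nerolidol" in part.major
        assert "Eucalyptol" in part.minor
        # cannabinoids and the aggregate never partition
        assert "Cannabidiol" not in part.major | part.minor
        assert "Total terpenes" not in part.major | part.minor

    def test_threshold_above_everything_empties_major(self):
        table = build_association_table(
            make_profile("most_effective", {"Myrcene": (0.3, 0.1)}),
            make_profile("least_effective", {"Myrcene": (0.2, 0.1)}),
        )
        part = partition_terpenes(table, threshold=10.0)
        assert part.major == frozenset() and part.minor == {"Myrcene"}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            partition_terpenes([], threshold=0.0)
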