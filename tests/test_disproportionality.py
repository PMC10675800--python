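"""2x2 tables, corrected RORs, Wald intervals and the Fisher exact test."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from faersig.disproportionality import (ContingencyTable, ReportIndex,
                                        compute_ror, fisher_exact_two_sided,
                                        haldane_correct, make_contingency,
                                        signal_for_pair, signal_table, wald_ci)
from oracles import fisher_two_sided_oracle


class TestMakeContingency:
    def test_other_reports_partition(self, ten_report_table):
        t = make_contingency(ten_report_table, "DRUGX", "EVENTY",
                             comparator="other_reports")
        assert t.cells == (3, 1, 2, 4)

    def test_all_reports_convention(self, ten_report_table):
        t = make_contingency(ten_report_table, "DRUGX", "EVENTY",
                             comparator="all_reports")
        assert t.cells == (3, 1, 5, 5)

    def test_drug_absent_from_vocabulary_raises(self, ten_report_table):
        with pytest.raises(KeyError, match="drug"):
            make_contingency(ten_report_table, "NOSUCH", "EVENTY")
        with pytest.raises(KeyError, match="preferred-term"):
            make_contingency(ten_report_table, "DRUGX", "NOSUCH")

    def test_drug_with_no_event_overlap(self, ten_report_table):
        t = make_contingency(ten_report_table, "DRUGZ", "EVENTY",
                             comparator="other_reports")
        assert t.a == 0 and t.b == 2


class TestHaldaneCorrection:
    def test_adds_half_to_every_cell(self):
        t = haldane_correct(ContingencyTable(10, 20, 30, 60))
        assert t.cells == (10.5, 20.5, 30.5, 60.5) and t.corrected

    def test_zero_table(self):
        assert haldane_correct(ContingencyTable(0, 0, 0, 0)).cells == (0.5,) * 4

    def test_double_correction_rejected(self):
        with pytest.raises(ValueError, match="already"):
            haldane_correct(haldane_correct(ContingencyTable(1, 2, 3, 4)))


class TestRor:
    def test_symmetric_table_gives_unit_ror(self):
        ror, lnror = compute_ror(ContingencyTable(5.5, 5.5, 5.5, 5.5, corrected=True))
        assert ror == 1.0 and lnror == 0.0

    def test_hand_evaluated_examples(self):
        ror, _ = compute_ror(haldane_correct(ContingencyTable(10, 20, 30, 60)))
        assert ror == pytest.approx(635.25 / 625.25, rel=1e-12)
        ror, _ = compute_ror(haldane_correct(ContingencyTable(0, 10, 50, 1000)))
        assert ror == pytest.approx(0.9434229137, rel=1e-9)

    def test_uncorrected_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="correct"):
            compute_ror(ContingencyTable(0, 10, 50, 1000))

    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_row_swap_inverts_ror(self, cells):
        """Swapping the drug and comparator rows maps lnROR to -lnROR."""
        a, b, c, d = cells
        t = haldane_correct(ContingencyTable(a, b, c, d))
        swapped = ContingencyTable(t.c, t.d, t.a, t.b, corrected=True)
        r1, l1 = compute_ror(t)
        r2, l2 = compute_ror(swapped)
        assert r2 == pytest.approx(1 / r1, rel=1e-12)
        assert l2 == pytest.approx(-l1, abs=1e-12)


class TestWaldCI:
    def test_symmetric_example(self):
        lo, hi = wald_ci(ContingencyTable(5.5, 5.5, 5.5, 5.5, corrected=True))
        assert lo == pytest.approx(0.187972, abs=1e-6)
        assert hi == pytest.approx(5.319945, abs=1e-5)

    def test_width_shrinks_with_scale(self):
        t = haldane_correct(ContingencyTable(10, 20, 30, 60))
        big = haldane_correct(ContingencyTable(1000, 2000, 3000, 6000))
        lo1, hi1 = wald_ci(t)
        lo2, hi2 = wald_ci(big)
        assert math.log(hi2 / lo2) < math.log(hi1 / lo1)

    def test_level_validation(self):
        t = ContingencyTable(5.5, 5.5, 5.5, 5.5, corrected=True)
        with pytest.raises(ValueError):
            wald_ci(t, level=1.2)

    def test_interval_brackets_ror_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            cells = rng.integers(0, 500, size=4)
            t = haldane_correct(ContingencyTable(*map(int, cells)))
            ror, _ = compute_ror(t)
            lo, hi = wald_ci(t)
            assert lo <= ror <= hi


class TestFisher:
    @pytest.mark.parametrize("cells, expected", [
        ((3, 1, 1, 3), 34 / 70),
        ((5, 0, 0, 5), 2 / 252),
        ((2, 2, 2, 2), 1.0),
    ])
    def test_enumerated_examples(self, cells, expected):
        assert fisher_exact_two_sided(cells) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_table_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            fisher_exact_two_sided((0, 0, 0, 0))

    def test_corrected_table_rejected(self):
        with pytest.raises(ValueError, match="raw"):
            fisher_exact_two_sided(haldane_correct(ContingencyTable(1, 2, 3, 4)))

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_matches_integer_enumeration_oracle(self, cells):
        if sum(cells) == 0:
            return
        p = fisher_exact_two_sided(cells)
        assert p == pytest.approx(fisher_two_sided_oracle(*cells), abs=1e-10)

    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_scipy(self, cells):
        """Independent cross-check against scipy's implementation."""
        from scipy.stats import fisher_exact
        if sum(cells) == 0:
            return
        a, b, c, d = cells
        p = fisher_exact_two_sided(cells)
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], abs=1e-9)


class TestSignalForPair:
    def test_composition_matches_components(self, ten_report_table):
        res = signal_for_pair(ten_report_table, "DRUGX", "EVENTY",
                              comparator="other_reports")
        t = haldane_correct(ContingencyTable(3, 1, 2, 4))
        ror, lnror = compute_ror(t)
        lo, hi = wald_ci(t)
        assert (res.a, res.b, res.c, res.d) == (3, 1, 2, 4)
        assert res.ror == pytest.approx(ror, rel=1e-12)
        assert res.lnror == pytest.approx(lnror, rel=1e-12)
        assert (res.ci_low, res.ci_high) == pytest.approx((lo, hi), rel=1e-12)
        assert res.p_value == pytest.approx(fisher_two_sided_oracle(3, 1, 2, 4), abs=1e-10)
        assert math.exp(res.lnror) == pytest.approx(res.ror, rel=1e-12)

    def test_fisher_always_uses_partition_cells(self, ten_report_table):
        """The comparator changes ROR cells, never the exact-test p."""
        r_all = signal_for_pair(ten_report_table, "DRUGX", "EVENTY", "all_reports")
        r_other = signal_for_pair(ten_report_table, "DRUGX", "EVENTY", "other_reports")
        assert r_all.p_value == r_other.p_value
        assert (r_all.c, r_all.d) == (5, 5)

    def test_degenerate_margin_yields_nan_p_not_significant(self, ten_report_table):
        """A drug with zero reports still gets a finite corrected ROR, but the
        exact test is undefined: p is NaN and the pair is never significant."""
        idx = ReportIndex(ten_report_table, drugs=["DRUGX", "UNSEEN"],
                          events=["EVENTY"])
        res = signal_for_pair(idx, "UNSEEN", "EVENTY")
        assert math.isnan(res.p_value)
        assert res.significant is False
        assert math.isfinite(res.lnror) and res.ror > 0

    def test_signal_table_order_and_consistency(self, ten_report_table):
        df = signal_table(ten_report_table, comparator="other_reports")
        assert list(df.columns[:6]) == ["drug", "pt", "a", "b", "c", "d"]
        assert df[["drug", "pt"]].apply(tuple, axis=1).is_monotonic_increasing
        for _, row in df.iterrows():
            res = signal_for_pair(ten_report_table, row["drug"], row["pt"],
                                  comparator="other_reports")
            assert row["lnror"] == pytest.approx(res.lnror, rel=1e-9)
            if not math.isnan(res.p_value):
                assert row["p_value"] == pytest.approx(res.p_value, abs=1e-12)
            assert np.exp(row["lnror"]) == pytest.approx(row["ror"], rel=1e-12)

    def test_event_total_column_counts_whole_database(self, ten_report_table):
        df = signal_table(ten_report_table)
        assert set(df.loc[df["pt"] == "EVENTY", "event_total"]) == {5}

    def test_pair_counts_bounded_by_n_reports(self, ten_report_table):
        idx = ReportIndex(ten_report_table)
        a, drug_totals, event_totals = idx.pair_counts()
        assert a.max() <= ten_report_table.n_reports
        assert drug_totals.max() <= ten_report_table.n_reports
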