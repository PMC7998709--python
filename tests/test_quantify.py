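"""Comparative-Ct arithmetic, the fluorescence-coefficient route, reporting."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluorct import (
    CtRecord,
    EmptyReportError,
    consolidate_table,
    delta_ct,
    delta_ct_table,
    delta_delta_ct,
    fold_change_consolidated,
    fold_change_fluorescent,
    fold_change_report,
)


def rec(sample, gene, role, ct, ft):
    return CtRecord(sample, gene, role, ct, ft)


class TestScalarOps:
    def test_delta_ct(self):
        assert delta_ct(30.0, 30.0) == 0.0
        assert delta_ct(35.2, 28.1) == pytest.approx(7.1)

    def test_delta_ct_missing_propagates(self):
        assert delta_ct(None, 28.1) is None
        assert delta_ct(30.0, None) is None

    def test_delta_delta_ct(self):
        assert delta_delta_ct(7.1, 7.1) == 0.0
        assert delta_delta_ct(5.0, 7.0) == -2.0
        assert delta_delta_ct(None, 7.0) is None

    def test_delta_delta_ct_antisymmetry(self):
        assert delta_delta_ct(5.0, 7.0) == -delta_delta_ct(7.0, 5.0)

    def test_fold_change_consolidated(self):
        assert fold_change_consolidated(7.1, 7.1) == pytest.approx(1.0)
        assert fold_change_consolidated(7.1, 10.1) == pytest.approx(8.0)
        assert fold_change_consolidated(10.1, 7.1) == pytest.approx(1 / 8.0)
        assert fold_change_consolidated(None, 7.1) is None


class TestFluorescentRoute:
    def test_equal_thresholds_reduce_to_plain_ddct(self):
        records = dict(
            t1=rec("S1", "T", "target", 30.0, 5000.0),
            c1=rec("S1", "C", "control", 25.0, 5000.0),
            t2=rec("S2", "T", "target", 32.0, 5000.0),
            c2=rec("S2", "C", "control", 25.0, 5000.0),
        )
        ddct = (30.0 - 25.0) - (32.0 - 25.0)
        out = fold_change_fluorescent(
            records["t1"], records["c1"], records["t2"], records["c2"]
        )
        assert out == pytest.approx(2.0 ** (-ddct), rel=1e-12)

    def test_hand_evaluated_example(self):
        """Coefficient (8000/12000)(12000/16000) = 1/2, ddCt = -2, ratio = 2."""
        out = fold_change_fluorescent(
            rec("S1", "T", "target", 30.0, 8000.0),
            rec("S1", "C", "control", 25.0, 12000.0),
            rec("S2", "T", "target", 32.0, 16000.0),
            rec("S2", "C", "control", 25.0, 12000.0),
        )
        assert out == pytest.approx(2.0, rel=1e-12)

    def test_undetected_input_gives_missing(self):
        out = fold_change_fluorescent(
            CtRecord.undetected("S1", "T"),
            rec("S1", "C", "control", 25.0, 12000.0),
            rec("S2", "T", "target", 32.0, 16000.0),
            rec("S2", "C", "control", 25.0, 12000.0),
        )
        assert out is None

    @given(
        ct=st.tuples(*[st.floats(2.0, 40.0)] * 4),
        ft=st.tuples(*[st.floats(10.0, 1e5)] * 4),
    )
    def test_identity_with_consolidation_route(self, ct, ft):
        """Eq-style coefficient route == consolidate-then-compare, always."""
        t1 = rec("S1", "T", "target", ct[0], ft[0])
        c1 = rec("S1", "C", "control", ct[1], ft[1])
        t2 = rec("S2", "T", "target", ct[2], ft[2])
        c2 = rec("S2", "C", "control", ct[3], ft[3])
        direct = fold_change_fluorescent(t1, c1, t2, c2)

        table = consolidate_table([t1, c1, t2, c2])
        dct = delta_ct_table(table, control_gene="C")
        by_sample = {e.sample_id: e.delta_ct for e in dct.entries}
        via_consolidation = fold_change_consolidated(by_sample["S1"], by_sample["S2"])
        assert direct == pytest.approx(via_consolidation, rel=1e-9)


@pytest.fixture
def consolidated_table():
    """Five samples, one target + control, all on common per-gene thresholds;
    S3's target and S5's control never amplified."""
    records = [
        rec("S1", "T", "target", 30.0, 8000.0),
        rec("S2", "T", "target", 27.0, 8000.0),
        CtRecord.undetected("S3", "T"),
        rec("S4", "T", "target", 33.5, 8000.0),
        rec("S5", "T", "target", 31.0, 8000.0),
        rec("S1", "C", "control", 25.0, 12000.0),
        rec("S2", "C", "control", 24.0, 12000.0),
        rec("S3", "C", "control", 25.5, 12000.0),
        rec("S4", "C", "control", 26.0, 12000.0),
        CtRecord.undetected("S5", "C"),
    ]
    return delta_ct_table(records)


class TestDeltaCtTable:
    def test_entries_and_flags(self, consolidated_table):
        by_sample = {e.sample_id: e for e in consolidated_table.entries}
        assert by_sample["S1"].delta_ct == pytest.approx(5.0)
        assert by_sample["S3"].delta_ct is None and not by_sample["S3"].expressed
        assert by_sample["S5"].delta_ct is None and not by_sample["S5"].normalizable
        assert consolidated_table.control_gene == "C"

    def test_mixed_thresholds_rejected(self):
        records = [
            rec("S1", "T", "target", 30.0, 8000.0),
            rec("S2", "T", "target", 27.0, 9000.0),
            rec("S1", "C", "control", 25.0, 12000.0),
            rec("S2", "C", "control", 24.0, 12000.0),
        ]
        with pytest.raises(ValueError, match="consolidate"):
            delta_ct_table(records)

    def test_control_gene_inferred_from_roles(self, consolidated_table):
        assert consolidated_table.control_gene == "C"


class TestFoldChangeReport:
    def test_auto_reference_is_highest_expression(self, consolidated_table):
        report = fold_change_report(consolidated_table)
        # S2 has the smallest delta Ct (3.0) hence the highest expression
        assert report.reference_sample_id == "S2"
        assert report.ratio("S2") == 1.0

    def test_ratios_and_logs(self, consolidated_table):
        report = fold_change_report(consolidated_table)
        # S1: dCt 5.0 vs reference 3.0 -> 2^-2
        assert report.ratio("S1") == pytest.approx(0.25, rel=1e-12)
        row = next(r for r in report.rows if r.sample_id == "S1")
        assert row.log10_fold_change == pytest.approx(math.log10(0.25), abs=1e-12)

    def test_non_expressed_and_non_normalizable_sections(self, consolidated_table):
        report = fold_change_report(consolidated_table)
        assert report.non_expressed == ("S3",)
        assert report.non_normalizable == ("S5",)
        assert all(r.sample_id != "S3" for r in report.rows)

    def test_explicit_reference(self, consolidated_table):
        report = fold_change_report(consolidated_table, reference="S1")
        assert report.ratio("S1") == 1.0
        assert report.ratio("S2") == pytest.approx(4.0, rel=1e-12)

    def test_auto_tie_breaks_lexicographically(self):
        records = [
            rec("SB", "T", "target", 30.0, 8000.0),
            rec("SA", "T", "target", 30.0, 8000.0),
            rec("SB", "C", "control", 25.0, 8000.0),
            rec("SA", "C", "control", 25.0, 8000.0),
        ]
        report = fold_change_report(delta_ct_table(records))
        assert report.reference_sample_id == "SA"

    def test_no_expressed_samples_is_an_error(self):
        records = [
            CtRecord.undetected("S1", "T"),
            rec("S1", "C", "control", 25.0, 8000.0),
        ]
        with pytest.raises(EmptyReportError):
            fold_change_report(delta_ct_table(records))

    def test_reference_invariance_of_pairwise_ratios(self, consolidated_table):
        """ratio_i / ratio_j is the same whatever reference sample is chosen."""
        expressed = ["S1", "S2", "S4"]
        ratios = {}
        for reference in expressed:
            report = fold_change_report(consolidated_table, reference=reference)
            ratios[reference] = {s: report.ratio(s) for s in expressed}
        for i in expressed:
            for j in expressed:
                values = [ratios[ref][i] / ratios[ref][j] for ref in expressed]
                assert max(values) == pytest.approx(min(values), rel=1e-9)

    def test_transitivity(self, consolidated_table):
        report = fold_change_report(consolidated_table)
        r = report.ratio
        assert (r("S1") / r("S2")) * (r("S2") / r("S4")) == pytest.approx(
            r("S1") / r("S4"), rel=1e-9
        )

    def test_log_column_matches_ratio_column(self, consolidated_table):
        report = fold_change_report(consolidated_table)
        for row in report.rows:
            assert row.log10_fold_change == pytest.approx(
                math.log10(row.fold_change_ratio), abs=1e-12
            )
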