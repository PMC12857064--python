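"""Unit and property tests for the 2x2 disproportionality statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvsignals.dispro import (
    ContingencyTable,
    bcpnn_ic,
    build_contingency,
    contingency_by_drug,
    ebgm,
    prr,
    reconstruct_table,
    ror,
    score_table,
)

cells = st.integers(min_value=1, max_value=2000)


class TestPointEstimates:
    def test_independence_table_all_statistics_are_null(self):
        r = score_table(ContingencyTable(10, 10, 10, 10))
        assert r.ror == pytest.approx(1.0)
        assert r.prr == pytest.approx(1.0)
        assert r.chi2 == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)
        assert r.ic == pytest.approx(0.0, abs=1e-12)
        assert r.ebgm == pytest.approx(1.0)
        lo, hi = r.ror_ci_low, r.ror_ci_high
        assert lo < 1 < hi

    def test_unit_table_ror_interval_matches_hand_evaluation(self):
        # se = sqrt(4) = 2, so the CI is exp(+-1.96*2) around 1
        point, lo, hi = ror(ContingencyTable(1, 1, 1, 1))
        assert point == pytest.approx(1.0)
        assert lo == pytest.approx(math.exp(-1.96 * 2))
        assert hi == pytest.approx(math.exp(1.96 * 2))

    def test_prr_with_empty_b_cell_by_hand(self):
        point, lo, hi, chi2, p = prr(ContingencyTable(2, 0, 1, 1))
        assert point == pytest.approx((2 / 2) / (1 / 2))

    @pytest.mark.parametrize(
        "table, field, printed",
        [
            # large-database rows with report-level totals reconstructed from
            # a case count, the event margin and the database size
            (ContingencyTable(2353, 761_944, 11_703, 17_851_667), "ror", 4.71),
            (ContingencyTable(2353, 762_060, 11_703, 17_851_551), "prr", 4.7),
            (ContingencyTable(2353, 762_060, 11_703, 17_851_551), "ebgm", 4.08),
            (ContingencyTable(2353, 762_060, 11_703, 17_851_551), "ic", 2.03),
            (ContingencyTable(251, 26_505 - 251, 14_056 - 251, 18_627_667 - 26_505 - 14_056 + 251), "ebgm", 12.55),
        ],
    )
    def test_published_scale_values(self, table, field, printed):
        r = score_table(table)
        ndigits = len(str(printed).split(".")[1])
        assert round(getattr(r, field), ndigits) == pytest.approx(printed)

    def test_zero_cells_flagged_not_estimable(self):
        r = score_table(ContingencyTable(0, 5, 5, 5))
        assert not r.estimable
        assert math.isnan(r.ror) and math.isnan(r.ic) and math.isnan(r.ebgm)

    def test_continuity_option_restores_estimability(self):
        r = score_table(ContingencyTable(0, 5, 5, 5), continuity=True)
        assert r.estimable
        # matches the explicitly corrected table
        direct = score_table(ContingencyTable(0.5, 5.5, 5.5, 5.5))
        assert r.ror == pytest.approx(direct.ror)

    def test_ic_fixed_offset_mode(self):
        t = ContingencyTable(50, 500, 300, 10_000)
        ic, ic025 = bcpnn_ic(t, method="fixed_offset", fixed_offset=1.67)
        assert ic025 == pytest.approx(ic - 1.67)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            ContingencyTable(-1, 1, 1, 1)


class TestInvariants:
    @settings(derandomize=True, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic_is_log2_of_ebgm(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ic, _ = bcpnn_ic(t)
        point, _ = ebgm(t)
        assert ic == pytest.approx(math.log2(point), rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ror_prr_ebgm_ordering_follows_cross_product_sign(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        r, _, _ = ror(t)
        p, _, _, _, _ = prr(t)
        e, _ = ebgm(t)
        cross = a * d - b * c
        if cross > 0:
            assert r > p > e > 1
        elif cross < 0:
            assert r < p < e < 1
        else:
            assert r == pytest.approx(p) == pytest.approx(e) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(1, 200), extra=st.integers(1, 500), d=cells)
    def test_points_strictly_increase_in_a_in_sparse_regime(self, a, extra, d):
        # sparse regime (b, c > a): the drug and the event are each minority
        # features of the database, as in spontaneous-report data
        b = c = a + extra
        lo = score_table(ContingencyTable(a, b, c, d))
        hi = score_table(ContingencyTable(a + 1, b, c, d))
        assert hi.ror > lo.ror
        assert hi.prr > lo.prr
        assert hi.ebgm > lo.ebgm
        assert hi.ic > lo.ic

    @settings(derandomize=True, max_examples=100)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ci_brackets_point(self, a, b, c, d):
        r = score_table(ContingencyTable(a, b, c, d))
        assert r.ror_ci_low <= r.ror <= r.ror_ci_high
        assert r.prr_ci_low <= r.prr <= r.prr_ci_high
        assert r.ebgm05 < r.ebgm


class TestContingencyConstruction:
    def test_four_report_enumeration(self):
        exposures = pd.DataFrame(
            {"record_id": ["r1", "r2"], "generic": ["D", "D"]}
        )
        t = build_contingency(exposures, flagged={"r1", "r3"}, drug="D", n_reports=4)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_repeated_role_lines_count_once(self):
        exposures = pd.DataFrame(
            {"record_id": ["r1", "r1", "r2"], "generic": ["D", "D", "E"]}
        )
        t = build_contingency(exposures, flagged={"r1"}, drug="D", n_reports=2)
        assert t.a == 1 and t.b == 0

    def test_absent_drug_gives_empty_margin(self):
        exposures = pd.DataFrame({"record_id": ["r1"], "generic": ["D"]})
        t = build_contingency(exposures, flagged={"r1"}, drug="missing", n_reports=2)
        assert t.drug_total == 0

    def test_by_drug_matches_single_drug_builder(self):
        rng = np.random.default_rng(3)
        n = 500
        recs = [f"r{i}" for i in range(n)]
        rows = []
        for i, r in enumerate(recs):
            for g in ("D1", "D2", "D3"):
                if rng.random() < 0.2:
                    rows.append((r, g))
        exposures = pd.DataFrame(rows, columns=["record_id", "generic"])
        flagged = {r for r in recs if rng.random() < 0.1}
        table = contingency_by_drug(exposures, flagged, n_reports=n)
        for g in table.index:
            t = build_contingency(exposures, flagged, g, n_reports=n)
            row = table.loc[g]
            assert (row.a, row.b, row.c, row.d) == (t.a, t.b, t.c, t.d)


class TestReconstruction:
    @pytest.mark.parametrize("anchor", ["ror", "prr", "ebgm"])
    def test_round_trip_recovers_cells(self, anchor):
        t = ContingencyTable(120, 4_880, 900, 994_100)
        stats = score_table(t)
        kwargs = {anchor: getattr(stats, anchor)}
        back = reconstruct_table(t.a, t.event_total, t.n, **kwargs)
        assert back.b == pytest.approx(t.b, rel=1e-10)
        assert back.d == pytest.approx(t.d, rel=1e-10)

    def test_requires_exactly_one_anchor(self):
        with pytest.raises(ValueError, match="exactly one"):
            reconstruct_table(10, 100, 1000, ror=2.0, prr=2.0)
        with pytest.raises(ValueError, match="exactly one"):
            reconstruct_table(10, 100, 1000)
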