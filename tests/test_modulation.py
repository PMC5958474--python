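"""Modulation calling, the genomic-risk index and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genorisk import datasets
from genorisk.modulation import (
    DOWN,
    HIGH_RISK,
    LOW_RISK,
    MEDIUM_RISK,
    UNCHANGED,
    UP,
    ComparisonTable,
    ModulationCalls,
    RiskAssessment,
    call_modulation,
    classify_risk,
    cohort_summary,
    count_modulated,
    direction_summary,
    read_comparison_tsv,
    risk_percent,
    round_half_away,
    write_comparison_tsv,
)


def make_table(rows, disease="d", disease_class="cancer"):
    df = pd.DataFrame(rows, columns=["gene", "fold_change", "p_value"])
    return ComparisonTable(
        disease=disease, disease_class=disease_class, tissue="t", geo_id="SYN001",
        rows=df,
    )


class TestCallModulation:
    def test_fold_change_thresholds(self, panel):
        table = make_table(
            [
                ("PARP1", 2.03, np.nan),   # reported up call
                ("MRE11A", 0.46, np.nan),  # reported down call
                ("ATM", 1.0, np.nan),
                ("ATR", 2.0, np.nan),      # boundary: >= 2 is up
                ("CHEK1", 0.5, np.nan),    # boundary: <= 0.5 is down
                ("CHEK2", 1.99, np.nan),
            ]
        )
        calls = call_modulation(table, panel)
        assert calls.labels["PARP1"] == UP
        assert calls.labels["MRE11A"] == DOWN
        assert calls.labels["ATM"] == UNCHANGED
        assert calls.labels["ATR"] == UP
        assert calls.labels["CHEK1"] == DOWN
        assert calls.labels["CHEK2"] == UNCHANGED

    def test_missing_genes_are_unchanged(self, panel):
        calls = call_modulation(make_table([("PARP1", 3.0, np.nan)]), panel)
        assert (calls.labels.drop("PARP1") == UNCHANGED).all()
        assert len(calls.labels) == 68

    def test_p_value_gates_the_call_when_present(self, panel):
        table = make_table([("PARP1", 3.0, 0.2), ("ATM", 3.0, 0.01)])
        calls = call_modulation(table, panel)
        assert calls.labels["PARP1"] == UNCHANGED
        assert calls.labels["ATM"] == UP

    def test_unknown_genes_ignored(self, panel, caplog):
        calls = call_modulation(make_table([("NOPE123", 9.0, np.nan)]), panel)
        assert (calls.labels == UNCHANGED).all()

    def test_invalid_fold_change_rejected(self, panel):
        with pytest.raises(ValueError):
            make_table([("PARP1", -1.0, np.nan)])

    def test_invalid_threshold_ordering_rejected(self, panel):
        with pytest.raises(ValueError):
            call_modulation(make_table([]), panel, up_fc=0.9)

    def test_bh_correction_tightens_calls(self, panel):
        # smallest p adjusts to 0.04 * 2 / 1 = 0.08 > alpha once a second
        # test enters the family, so the up call disappears
        rows = [("PARP1", 3.0, 0.04), ("ATM", 3.0, 0.9)]
        plain = call_modulation(make_table(rows), panel)
        corrected = call_modulation(make_table(rows), panel, bh_correct=True)
        assert (plain.labels == UP).sum() == 1
        assert (corrected.labels == UP).sum() == 0

    @given(
        fcs=st.lists(
            st.floats(min_value=0.05, max_value=20.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_match_brute_force_scan(self, panel, fcs):
        genes = list(panel.symbols)[: len(fcs)]
        table = make_table([(g, fc, np.nan) for g, fc in zip(genes, fcs)])
        calls = call_modulation(table, panel)
        n_up, n_down = count_modulated(calls, panel, "both")
        assert n_up == sum(1 for fc in fcs if fc >= 2.0)
        assert n_down == sum(1 for fc in fcs if fc <= 0.5)


class TestCountModulated:
    def test_category_restriction(self, panel):
        table = make_table([("PARP1", 3.0, np.nan), ("MLH1", 0.3, np.nan)])
        calls = call_modulation(table, panel)
        assert count_modulated(calls, panel, "DDCF") == (1, 0)
        assert count_modulated(calls, panel, "DDRF") == (0, 1)
        assert count_modulated(calls, panel, "both") == (1, 1)

    def test_empty_table(self, panel):
        calls = call_modulation(make_table([]), panel)
        assert count_modulated(calls, panel, "both") == (0, 0)


class TestRiskIndex:
    @pytest.mark.parametrize(
        "n, display",
        [(18, 26), (16, 24), (13, 19), (12, 18), (10, 15), (9, 13), (7, 10),
         (6, 9), (4, 6), (3, 4), (2, 3), (1, 1), (0, 0), (68, 100)],
    )
    def test_display_rounding(self, n, display):
        raw, disp = risk_percent(n)
        assert disp == display
        assert raw == pytest.approx(100.0 * n / 68)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            risk_percent(69)
        with pytest.raises(ValueError):
            risk_percent(-1)

    @pytest.mark.parametrize(
        "raw, group",
        [
            (100 * 18 / 68, HIGH_RISK),   # 26.47
            (100 * 7 / 68, HIGH_RISK),    # 10.29: 7-gene diseases are high
            (10.0, HIGH_RISK),
            (9.999, MEDIUM_RISK),
            (100 * 6 / 68, MEDIUM_RISK),  # 8.82
            (5.0, MEDIUM_RISK),
            (4.999, LOW_RISK),
            (0.0, LOW_RISK),
        ],
    )
    def test_group_boundaries(self, raw, group):
        assert classify_risk(raw) == group

    def test_adding_a_modulated_gene_is_monotone(self):
        order = {LOW_RISK: 0, MEDIUM_RISK: 1, HIGH_RISK: 2}
        prev_raw, prev_rank = -1.0, 0
        for n in range(69):
            raw, _ = risk_percent(n)
            rank = order[classify_risk(raw)]
            assert raw > prev_raw
            assert rank >= prev_rank
            prev_raw, prev_rank = raw, rank

    def test_half_away_rounding_convention(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(2.5) == 3
        assert round_half_away(-0.5) == -1
        assert round_half_away(75.85, 1) == 75.9


class TestSummaries:
    @pytest.mark.parametrize(
        "up, changes, expected",
        [(44, 58, 75.9), (32, 45, 71.1), (0, 10, 0.0)],
    )
    def test_direction_summary_percentages(self, panel, up, changes, expected):
        genes = list(panel.category_symbols("DDCF"))
        # spread the up/down calls over as many synthetic contrasts as needed
        calls_list = []
        remaining_up, remaining_down = up, changes - up
        while remaining_up + remaining_down > 0:
            take_up = min(remaining_up, len(genes))
            take_down = min(remaining_down, len(genes) - take_up)
            labels = pd.Series(UNCHANGED, index=list(panel.symbols), dtype=object)
            labels[genes[:take_up]] = UP
            labels[genes[take_up : take_up + take_down]] = DOWN
            calls_list.append(
                ModulationCalls(disease=f"d{len(calls_list)}",
                                disease_class="cancer", labels=labels)
            )
            remaining_up -= take_up
            remaining_down -= take_down
        total_up, total_changes, percent = direction_summary(
            calls_list, panel, "DDCF"
        )
        assert (total_up, total_changes) == (up, changes)
        assert percent == expected

    def test_direction_summary_no_changes_is_missing(self, panel):
        labels = pd.Series(UNCHANGED, index=list(panel.symbols), dtype=object)
        calls = ModulationCalls(disease="d", disease_class="cancer", labels=labels)
        assert direction_summary([calls], panel, "DDRF") == (0, 0, None)

    def test_cohort_summary_partition(self):
        assessments = [
            RiskAssessment(f"d{i}", "inflammation", n_up=n, n_down=0)
            for i, n in enumerate([18, 7, 6, 6, 4, 3, 0])
        ]
        summary = cohort_summary(assessments, "inflammation")
        assert summary["count"].sum() == len(assessments)
        assert summary.loc["high", "count"] == 2
        assert summary.loc["medium", "count"] == 3
        assert summary.loc["low", "count"] == 2

    def test_single_quiet_disease_is_all_low(self):
        a = RiskAssessment("quiet", "inflammation", n_up=0, n_down=0)
        summary = cohort_summary([a])
        assert summary.loc["low", "count"] == 1
        assert summary.loc["low", "percent"] == 100.0


class TestComparisonIO:
    def test_tsv_round_trip(self, tmp_path):
        table = make_table(
            [("PARP1", 2.5, 0.01), ("ATM", 0.4, np.nan)],
            disease="test disease",
        )
        path = tmp_path / "cmp.tsv"
        write_comparison_tsv(table, path)
        back = read_comparison_tsv(path)
        assert back.disease == "test disease"
        assert back.disease_class == "cancer"
        assert back.geo_id == "SYN001"
        pd.testing.assert_frame_equal(back.rows, table.rows)
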