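"""Statistical tests, Bonferroni display convention, and the report table."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from rmekit.stats import (
    ReportRow,
    anova_gate,
    bonferroni,
    build_report,
    paired_t,
    render_report_text,
    round_up_1sf,
    unpaired_t,
)


def _paired_t_oracle(before, after):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)); p from the t CDF."""
    d = np.asarray(after, float) - np.asarray(before, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * (1 - special.stdtr(n - 1, abs(t)))
    return t, p


def _welch_oracle(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (b.mean() - a.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * (1 - special.stdtr(df, abs(t)))
    return t, p


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0
        assert res.degenerate

    def test_constant_shift_detected(self):
        """A perfectly consistent shift (27,29,28)->(66,68,67) is significant."""
        res = paired_t([27.0, 29.0, 28.0], [66.0, 68.0, 67.0])
        assert res.p_corrected < 0.01

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            before = rng.normal(30, 5, n)
            after = before + rng.normal(2, 4, n)
            res = paired_t(before, after)
            t_ref, p_ref = _paired_t_oracle(before, after)
            assert res.statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.p_raw == pytest.approx(p_ref, abs=1e-10)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            paired_t([1.0], [2.0])

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestUnpairedT:
    def test_identical_groups(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        res = unpaired_t([1.0, 1.1, 0.9], [2.6, 2.8, 2.7])
        assert res.p_corrected < 0.05

    def test_matches_welch_formula(self, rng):
        for _ in range(50):
            a = rng.normal(10, 2, int(rng.integers(3, 8)))
            b = rng.normal(12, 4, int(rng.integers(3, 8)))
            res = unpaired_t(a, b)
            t_ref, p_ref = _welch_oracle(a, b)
            assert res.statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.p_raw == pytest.approx(p_ref, abs=1e-10)

    def test_n1_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            unpaired_t([1.0], [2.0, 3.0])


class TestAnovaGate:
    def test_identical_groups_fail_gate(self):
        g = [[10.0, 11.0, 12.0]] * 3
        res = anova_gate(g)
        assert not res.passed

    def test_separated_group_passes_gate(self):
        res = anova_gate([[10.0, 11.0, 12.0], [10.5, 11.5, 12.5],
                          [30.0, 31.0, 32.0]])
        assert res.passed
        assert res.kind == "repeated-measures"

    def test_matches_statsmodels_repeated_measures(self, rng):
        """Hand-rolled within-subject ANOVA equals statsmodels AnovaRM."""
        from statsmodels.stats.anova import AnovaRM

        for _ in range(10):
            n, k = int(rng.integers(3, 8)), int(rng.integers(3, 5))
            data = rng.normal(20, 5, (n, k))
            res = anova_gate([data[:, j] for j in range(k)])
            long = pd.DataFrame(
                [(i, j, data[i, j]) for i in range(n) for j in range(k)],
                columns=["subject", "cond", "value"],
            )
            sm = AnovaRM(long, "value", "subject", within=["cond"]).fit()
            assert res.F == pytest.approx(
                float(sm.anova_table["F Value"].iloc[0]), rel=1e-10
            )
            assert res.p == pytest.approx(
                float(sm.anova_table["Pr > F"].iloc[0]), abs=1e-10
            )

    def test_unbalanced_falls_back_to_one_way(self, caplog):
        with caplog.at_level("WARNING"):
            res = anova_gate([[1.0, 2.0], [1.5, 2.5, 3.0], [9.0, 10.0]])
        assert res.kind == "one-way"
        assert "unbalanced" in caplog.text

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            anova_gate([[1.0, 2.0], [3.0, 4.0]])


class TestBonferroni:
    def test_multiplication_and_cap(self):
        np.testing.assert_allclose(
            bonferroni([0.0003, 0.5], m=3), [0.0009, 1.0]
        )

    def test_m_smaller_than_comparisons_rejected(self):
        with pytest.raises(ValueError, match="m must be"):
            bonferroni([0.01, 0.02, 0.03], m=2)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.0009, 0.0009), (0.00102, 0.002), (0.34, 0.4), (0.7, 0.7),
         (0.96, 1.0), (1.0, 1.0), (0.0007, 0.0007)],
    )
    def test_round_up_one_significant_figure(self, p, expected):
        assert round_up_1sf(p) == pytest.approx(expected, rel=1e-12)

    def test_threshold_comparison_display(self):
        """Raw p 0.0003 at m=3 markers displays as 0.0009 (not 0.001)."""
        p_c = bonferroni([0.0003], m=3)[0]
        assert round_up_1sf(p_c) == pytest.approx(0.0009)


def _mk_test(p_corrected, n=3):
    from rmekit.stats import TestResult as _TR

    return _TR(comparison="x", statistic=5.0, p_raw=p_corrected / 2,
                      p_corrected=p_corrected, n=n, paired=True)


class TestReport:
    def test_significant_increase_called_yes(self):
        row = ReportRow(label="untreated", iso_mean=28.77, iso_sem=6.78,
                        hypo_mean=78.84, hypo_sem=1.84, test=_mk_test(0.01))
        assert row.translocation == "Yes"

    def test_non_significant_called_no(self):
        row = ReportRow(label="PKA inhibitor", iso_mean=25.62, iso_sem=5.16,
                        hypo_mean=33.66, hypo_sem=6.62, test=_mk_test(0.4))
        assert row.translocation == "No"

    def test_significant_decrease_called_no_and_flagged(self):
        row = ReportRow(label="odd", iso_mean=60.0, iso_sem=2.0,
                        hypo_mean=30.0, hypo_sem=2.0, test=_mk_test(0.01))
        table = build_report([row])
        assert table.loc[0, "translocation"] == "No"
        assert "significant-decrease" in table.loc[0, "flags"]

    def test_gate_failure_blocks_yes(self):
        row = ReportRow(label="x", iso_mean=20.0, iso_sem=2.0, hypo_mean=70.0,
                        hypo_sem=2.0, test=_mk_test(0.001), gate_passed=False)
        assert row.translocation == "No"

    def test_missing_area_rendered_na(self):
        row = ReportRow(label="S52D-like", iso_mean=20.0, iso_sem=2.0,
                        hypo_mean=22.0, hypo_sem=2.0, test=_mk_test(0.9))
        table = build_report([row])
        assert table.loc[0, "area_change_pct"] == "NA"

    def test_formatting_mean_sem_star(self):
        row = ReportRow(label="untreated", iso_mean=28.77, iso_sem=6.78,
                        hypo_mean=78.84, hypo_sem=1.84, test=_mk_test(0.001),
                        area_mean=145.19, area_sem=1.11,
                        area_test=_mk_test(0.002))
        table = build_report([row])
        assert table.loc[0, "isotonic_rme"] == "28.77 (6.78)"
        assert table.loc[0, "hypotonic_rme"] == "78.84 (1.84)*"
        assert table.loc[0, "area_change_pct"] == "145.19 (1.11)*"
        assert table.loc[0, "translocation"] == "Yes"

    def test_csv_round_trip_preserves_numbers(self, tmp_path):
        rows = [
            ReportRow(label="a", iso_mean=25.98, iso_sem=5.32, hypo_mean=33.07,
                      hypo_sem=5.24, test=_mk_test(0.7)),
            ReportRow(label="b", iso_mean=25.98, iso_sem=5.32, hypo_mean=63.61,
                      hypo_sem=6.16, test=_mk_test(0.0007)),
        ]
        table = build_report(rows)
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path, keep_default_na=False, dtype=str)
        pd.testing.assert_frame_equal(back, table)
        text = render_report_text(table, m=2)
        assert "Bonferroni m = 2" in text
        assert "63.61 (6.16)*" in text
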