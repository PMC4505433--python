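"""Statistical testing and translocation report assembly.

The decision pipeline mirrors standard practice for repeated tonicity
challenges of the same cells: a one-way repeated-measures ANOVA gates the
pairwise comparisons; paired t tests compare conditions within repeats (or
Welch t tests for independent samples, e.g. biotinylation of different
dishes); p values receive Bonferroni's correction over the planned
comparisons and are displayed rounded UP to one significant figure;
p < 0.05 (after correction) is significant. A condition is called
"translocation: yes" iff its hypotonic-vs-isotonic paired test is significant
AND the hypotonic mean RME exceeds the isotonic mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "GateResult",
    "ReportRow",
    "paired_t",
    "unpaired_t",
    "anova_gate",
    "bonferroni",
    "round_up_1sf",
    "build_report",
    "render_report_text",
]

ALPHA = 0.05


@dataclass
class TestResult:
    comparison: str
    statistic: float
    p_raw: float
    p_corrected: float
    n: int
    paired: bool
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA

    @property
    def p_display(self) -> str:
        return format_p(round_up_1sf(self.p_corrected))


@dataclass
class GateResult:
    passed: bool
    F: float
    p: float
    kind: str  # "repeated-measures" or "one-way"


def paired_t(before, after, comparison: str = "", m: int = 1) -> TestResult:
    """Two-sided paired t test on matched repeat values.

    Zero-variance differences are degenerate: p = 1 when all differences are
    zero (no effect whatsoever), otherwise the result is flagged degenerate
    with p = 0 (a perfectly consistent nonzero shift).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after must have equal length")
    if b.size < 2:
        raise ValueError("paired t test needs n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return _corrected(TestResult(comparison, 0.0, 1.0, 1.0, b.size, True,
                                         degenerate=True), m)
        return _corrected(TestResult(comparison, math.inf, 0.0, 0.0, b.size, True,
                                     degenerate=True), m)
    t, p = sps.ttest_rel(a, b)
    return _corrected(TestResult(comparison, float(t), float(p), float(p),
                                 b.size, True), m)


def unpaired_t(
    group_a, group_b, comparison: str = "", m: int = 1, equal_var: bool = False
) -> TestResult:
    """Two-sided unpaired t test (Welch by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired t test needs n >= 2 in each group")
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        equal = np.allclose(a.mean(), b.mean())
        return _corrected(
            TestResult(comparison, 0.0 if equal else math.inf,
                       1.0 if equal else 0.0, 1.0 if equal else 0.0,
                       min(a.size, b.size), False, degenerate=True), m)
    t, p = sps.ttest_ind(b, a, equal_var=equal_var)
    return _corrected(TestResult(comparison, float(t), float(p), float(p),
                                 min(a.size, b.size), False), m)


def _corrected(res: TestResult, m: int) -> TestResult:
    res.p_corrected = float(min(1.0, m * res.p_raw))
    return res


def anova_gate(groups: list, subjects_matched: bool = True) -> GateResult:
    """One-way ANOVA gate over >= 3 condition vectors.

    With matched subjects (the same cells measured under every condition,
    which requires equal group lengths) a repeated-measures ANOVA is used;
    unbalanced input falls back to an ordinary one-way ANOVA with a warning.
    Pairwise tests should only be interpreted when the gate passes.
    """
    if len(groups) < 3:
        raise ValueError("ANOVA gate needs at least 3 groups (use a t test)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    balanced = len({a.size for a in arrays}) == 1
    if subjects_matched and balanced:
        F, p = _repeated_measures_anova(arrays)
        kind = "repeated-measures"
    else:
        if subjects_matched and not balanced:
            log.warning(
                "unbalanced repeated-measures input; falling back to one-way ANOVA"
            )
        F, p = sps.f_oneway(*arrays)
        kind = "one-way"
    return GateResult(passed=bool(p < ALPHA), F=float(F), p=float(p), kind=kind)


def _repeated_measures_anova(arrays: list[np.ndarray]) -> tuple[float, float]:
    """Classic within-subject one-way ANOVA (subject = index within group)."""
    data = np.column_stack(arrays)  # subjects x conditions
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    tiny = 1e-12 * max(ss_tot, 1.0)
    if ss_cond <= tiny:  # no between-condition variation at all
        return 0.0, 1.0
    if ss_err <= tiny:  # perfectly consistent condition effect
        return math.inf, 0.0
    F = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_cond, df_err))
    return float(F), p


def bonferroni(p_raw, m: int) -> np.ndarray:
    """Bonferroni correction: p_c = min(1, m * p) per comparison."""
    p = np.asarray(p_raw, dtype=float)
    if m < p.size:
        raise ValueError("m must be at least the number of comparisons made")
    return np.minimum(1.0, m * p)


def round_up_1sf(p: float) -> float:
    """Round a p value UP to one significant figure (0.00102 -> 0.002)."""
    if p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    exp = math.floor(math.log10(p))
    lead = p / 10**exp
    lead_up = math.ceil(lead - 1e-12)
    if lead_up == 10:
        lead_up, exp = 1, exp + 1
    return float(min(1.0, float(f"{lead_up}e{exp}")))


def format_p(p: float) -> str:
    if p >= 1:
        return "1"
    return np.format_float_positional(p, trim="-")


@dataclass
class ReportRow:
    """One table row: a condition arm with its RME shift and call."""

    label: str
    iso_mean: float
    iso_sem: float
    hypo_mean: float
    hypo_sem: float
    test: TestResult
    area_mean: float | None = None
    area_sem: float | None = None
    area_test: TestResult | None = None
    surface_pct: float | None = None
    surface_pct_sem: float | None = None
    surface_test: TestResult | None = None
    gate_passed: bool = True
    flags: tuple[str, ...] = ()

    @property
    def translocation(self) -> str:
        sig = self.test.significant and self.gate_passed
        if sig and self.hypo_mean > self.iso_mean:
            return "Yes"
        return "No"


def build_report(rows: list[ReportRow]) -> pd.DataFrame:
    """Assemble the translocation table (one row per condition arm).

    A significant DECREASE in RME is still called "No" (the call requires an
    increase) and flagged anomalous. Missing area data renders as NA.
    """
    records = []
    for r in rows:
        anomalous = (
            r.test.significant and r.gate_passed and r.hypo_mean <= r.iso_mean
        )
        if anomalous:
            r.flags = r.flags + ("significant-decrease",)
            log.warning("row %s: significant RME decrease; called No", r.label)
        sig = "*" if (r.test.significant and r.gate_passed) else ""
        area_sig = (
            "*" if (r.area_test is not None and r.area_test.significant
                    and r.gate_passed) else ""
        )
        surf_sig = (
            "*" if (r.surface_test is not None and r.surface_test.significant)
            else ""
        )
        records.append(
            dict(
                label=r.label,
                isotonic_rme=f"{r.iso_mean:.2f} ({r.iso_sem:.2f})",
                hypotonic_rme=f"{r.hypo_mean:.2f} ({r.hypo_sem:.2f}){sig}",
                area_change_pct=(
                    "NA" if r.area_mean is None
                    else f"{r.area_mean:.2f} ({r.area_sem:.2f}){area_sig}"
                ),
                translocation=r.translocation,
                surface_pct_of_reference=(
                    "NA" if r.surface_pct is None
                    else f"{r.surface_pct:.1f} ({r.surface_pct_sem:.1f}){surf_sig}"
                ),
                p_display=r.test.p_display,
                flags=",".join(r.flags),
            )
        )
    return pd.DataFrame.from_records(records)


def render_report_text(table: pd.DataFrame, m: int | None = None) -> str:
    """Fixed-width text rendering of the report table."""
    buf = StringIO()
    cols = list(table.columns)
    widths = {
        c: max(len(c), *(len(str(v)) for v in table[c])) if len(table) else len(c)
        for c in cols
    }
    buf.write("  ".join(c.ljust(widths[c]) for c in cols) + "\n")
    buf.write("  ".join("-" * widths[c] for c in cols) + "\n")
    for _, row in table.iterrows():
        buf.write("  ".join(str(row[c]).ljust(widths[c]) for c in cols) + "\n")
    if m is not None:
        buf.write(f"\nBonferroni m = {m} planned comparisons; "
                  "* p < 0.05 after correction\n")
    return buf.getvalue()
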