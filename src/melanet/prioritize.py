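"""Statistical prioritization of articulation proteins up-expressed in cases.

For each articulation protein present in the expression matrix, a one-sided
Wilcoxon rank-sum test asks whether its expression in case samples exceeds
that in controls (alternative: case > control). P-values are adjusted by the
Benjamini–Hochberg step-up procedure within the articulation-protein family,
and proteins with adjusted p below alpha are flagged as prioritized targets.

The rank-sum p-value is exact (full enumeration over rank assignments) when
the combined sample size is at most 12 and there are no ties; otherwise the
normal approximation with midrank tie correction and continuity correction
is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import LabeledExpression

EXACT_N_MAX = 12
ALPHA_DEFAULT = 0.05


@dataclass
class WilcoxonResult:
    """Per-gene rank-sum results restricted to the articulation proteins."""

    table: pd.DataFrame  # columns: statistic, p, adjusted_p, selected
    missing: list[str]   # APs absent from the expression matrix

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def wilcoxon_one_sided(case_values, control_values) -> tuple[float, float]:
    """One-sided rank-sum test of case > control.

    Returns the Mann–Whitney U statistic for the case group and the p-value.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([case, control])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_N_MAX and no_ties) else "asymptotic"
    result = stats.mannwhitneyu(
        case, control, alternative="greater", method=method, use_continuity=True
    )
    return float(result.statistic), float(result.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_up_articulation_proteins(
    expr: LabeledExpression, aps, alpha: float = ALPHA_DEFAULT
) -> WilcoxonResult:
    """Test each articulation protein for elevated case expression.

    The multiple-testing family is the articulation-protein set itself.
    APs missing from the matrix are reported in ``missing``; if none are
    present the call fails.
    """
    aps = sorted(set(aps), key=str)
    present = [g for g in aps if g in expr.values.index]
    missing = [g for g in aps if g not in expr.values.index]
    if not present:
        raise ValueError("no articulation protein present in the expression matrix")
    case_cols = expr.case_samples
    control_cols = expr.control_samples
    stats_p = [
        wilcoxon_one_sided(
            expr.values.loc[g, case_cols], expr.values.loc[g, control_cols]
        )
        for g in present
    ]
    statistic = [s for s, _ in stats_p]
    raw_p = [p for _, p in stats_p]
    adjusted = bh_adjust(raw_p)
    table = pd.DataFrame(
        {
            "statistic": statistic,
            "p": raw_p,
            "adjusted_p": adjusted,
            "selected": adjusted < alpha,
        },
        index=present,
    )
    return WilcoxonResult(table.sort_values("adjusted_p"), missing)
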