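"""Differential expression on protein abundance tables and small assay maths.

The entry point is an :class:`AbundanceTable` of per-condition replicate
reporter intensities (e.g. time points 0 h / 24 h / 48 h). For each ordered
contrast (numerator condition, denominator condition) the module computes the
fold change of replicate means, a pooled-variance Student's t-test, and a
three-way call::

    up   iff  FC >= 1.5  and p < 0.05
    down iff  FC <= 2/3  and p < 0.05
    none otherwise

Boundary inclusivity is exactly as written: the fold-change cutoffs are
inclusive, the p cutoff strict. Cross-contrast set logic (union, intersection,
pairwise overlaps) and the intersection with network-predicted targets sit on
top. Two closed-form assay helpers are included: relative qPCR expression by
the 2^-ddCt rule and total glutathione from GSH/GSSG concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

FC_UP_DEFAULT = 1.5
FC_DOWN_DEFAULT = 2.0 / 3.0
ALPHA_DEFAULT = 0.05


@dataclass
class AbundanceTable:
    """Protein × replicate abundance matrix with condition groupings.

    ``values`` columns follow the ``<condition>_rep<i>`` convention;
    ``conditions`` maps each condition label to its replicate columns.
    """

    values: pd.DataFrame
    conditions: dict[str, list[str]]

    def __post_init__(self) -> None:
        for cond, cols in self.conditions.items():
            missing = [c for c in cols if c not in self.values.columns]
            if missing:
                raise ValueError(f"condition {cond!r} missing columns {missing}")
            if len(cols) < 2:
                raise ValueError(f"condition {cond!r} needs >=2 replicates")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    def replicates(self, condition: str) -> pd.DataFrame:
        return self.values[self.conditions[condition]]

    @classmethod
    def from_wide(cls, values: pd.DataFrame) -> "AbundanceTable":
        """Infer condition groupings from ``<condition>_rep<i>`` column names."""
        conditions: dict[str, list[str]] = {}
        for col in values.columns:
            cond, sep, _ = col.rpartition("_rep")
            if not sep:
                raise ValueError(f"column {col!r} not in <condition>_rep<i> form")
            conditions.setdefault(cond, []).append(col)
        return cls(values, conditions)


def read_abundance(path) -> AbundanceTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return AbundanceTable.from_wide(values)


def write_abundance(table: AbundanceTable, path) -> None:
    table.values.to_csv(path, sep="\t", index_label="protein_id")


def fold_change(
    table: AbundanceTable, contrast: tuple[str, str]
) -> pd.Series:
    """Per-protein ratio of replicate means, numerator over denominator.

    Zero denominator means yield NaN and are flagged via the returned
    series' name metadata; callers treat NaN as undefined.
    """
    num, den = contrast
    num_mean = table.replicates(num).mean(axis=1)
    den_mean = table.replicates(den).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num_mean / den_mean
    ratio[den_mean == 0] = np.nan
    ratio.name = f"{num}_vs_{den}"
    return ratio


def t_test(group_a, group_b) -> float:
    """Two-sided Student's t-test p-value (pooled variance).

    Degenerate zero-variance inputs follow the convention: equal means give
    p = 1 (no evidence), unequal means with zero spread give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def dep_filter(
    fold_change: float,
    p: float,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> str:
    """Three-way differential-expression call from a fold change and p-value."""
    if not (np.isfinite(fold_change) and np.isfinite(p)):
        return "none"
    if p < alpha and fold_change >= fc_up:
        return "up"
    if p < alpha and fold_change <= fc_down:
        return "down"
    return "none"


def dep_table(
    table: AbundanceTable,
    contrasts: list[tuple[str, str]],
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Fold changes, t-test p-values and calls for every protein × contrast.

    Returns a long-form frame with columns ``protein``, ``contrast``,
    ``fold_change``, ``p``, ``call``. ``log_transform`` applies log2(x+1) to
    intensities before the t-test only; fold changes stay on the linear scale.
    """
    records = []
    for num, den in contrasts:
        fc_series = fold_change(table, (num, den))
        num_vals = table.replicates(num)
        den_vals = table.replicates(den)
        if log_transform:
            num_vals = np.log2(num_vals + 1.0)
            den_vals = np.log2(den_vals + 1.0)
        for protein in table.protein_ids:
            p = t_test(num_vals.loc[protein], den_vals.loc[protein])
            fc = float(fc_series.loc[protein])
            records.append(
                {
                    "protein": protein,
                    "contrast": fc_series.name,
                    "fold_change": fc,
                    "p": p,
                    "call": dep_filter(fc, p, fc_up, fc_down, alpha),
                }
            )
    return pd.DataFrame.from_records(records)


def deps_per_contrast(dep_frame: pd.DataFrame) -> dict[str, set[str]]:
    """DEP identifier set for each contrast (calls other than ``none``)."""
    out: dict[str, set[str]] = {}
    for contrast, group in dep_frame.groupby("contrast", sort=False):
        out[contrast] = set(group.loc[group["call"] != "none", "protein"])
    return out


def contrast_set_ops(
    dep_sets: dict[str, set[str]]
) -> tuple[set[str], set[str], dict[tuple[str, str], int]]:
    """Union, intersection and pairwise overlap counts across contrasts."""
    if len(dep_sets) < 2:
        raise ValueError("need >=2 contrasts for set operations")
    sets = list(dep_sets.values())
    union = set().union(*sets)
    intersection = set.intersection(*sets)
    overlaps = {
        (a, b): len(dep_sets[a] & dep_sets[b])
        for a, b in combinations(dep_sets, 2)
    }
    return union, intersection, overlaps


def intersect_with_targets(
    dep_frame: pd.DataFrame,
    dep_union: set[str],
    ap_layers: dict[str, int],
) -> pd.DataFrame:
    """Join DEP evidence with articulation-protein evidence.

    ``ap_layers`` maps articulation proteins to their removal layer. Members
    of the overlap carry every contrast's fold change and call plus the layer.
    A zero overlap between nonempty mapped inputs suggests an identifier
    namespace mismatch and is worth a warning upstream.
    """
    overlap = sorted(dep_union & set(ap_layers))
    rows = []
    for protein in overlap:
        entry: dict[str, object] = {"protein": protein, "ap_layer": ap_layers[protein]}
        sub = dep_frame[dep_frame["protein"] == protein]
        for _, rec in sub.iterrows():
            entry[f"fc_{rec['contrast']}"] = rec["fold_change"]
            entry[f"call_{rec['contrast']}"] = rec["call"]
        rows.append(entry)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["ap_layer", "protein"]).reset_index(drop=True)
    return frame


def total_gsh(c_gsh: float, c_gssg: float) -> float:
    """Total glutathione: free GSH plus two per oxidized dimer (GSSG)."""
    if c_gsh < 0 or c_gssg < 0:
        raise ValueError("concentrations must be non-negative")
    return c_gsh + 2.0 * c_gssg


def ddct_expression(delta_delta_ct: float) -> float:
    """Relative qPCR expression by the 2^-ddCt rule."""
    return float(2.0 ** (-delta_delta_ct))
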