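"""Phenotype statistics for mutant-line comparisons.

Seed phytic acid, inorganic phosphate, oil content and yield-related
traits measured on replicate plants per line are compared with a
one-way fixed-effects ANOVA on line, followed by Tukey's HSD for all
pairwise contrasts and a compact letter display (lines sharing a letter
are not significantly different at alpha).  Also includes the two
bookkeeping formulas of a transformation experiment: transformation
efficiency and percent change versus a control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ComparisonResult",
    "transformation_efficiency",
    "percent_change",
    "fold_change",
    "anova_tukey",
    "compact_letter_display",
]


def transformation_efficiency(n_independent_transgenics: int, n_explants: int) -> float:
    """Percent of explants yielding independent transgenic events.

    100 x (independent transgenic plants / explants), to one decimal.
    """
    if n_explants <= 0:
        raise ValueError("zero explants")
    if not 0 <= n_independent_transgenics <= n_explants:
        raise ValueError("transgenic count must be between 0 and explant count")
    return round(100.0 * n_independent_transgenics / n_explants, 1)


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """Signed percent change of treatment versus control.

    Negative values are reductions: a treatment at 65% of control gives
    -35.0 (a "35% reduction").
    """
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def fold_change(treatment_mean: float, control_mean: float) -> float:
    """Fold change (treatment / control); 1 + percent_change/100."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return treatment_mean / control_mean


def compact_letter_display(
    groups: list[str],
    means: dict[str, float],
    significant: set[frozenset],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starting from one column containing every group, each significantly
    different pair splits any column containing both; columns that are
    subsets of others are absorbed.  The result satisfies both
    directions: groups sharing a letter are never significantly
    different, and every non-significant pair shares at least one
    letter.  Letters follow descending group means for readability.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(significant, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, strict subsets, and duplicates
        columns = []
        for c in new_columns:
            if not c or any(c < d for d in new_columns):
                continue
            if c not in columns:
                columns.append(c)
    # assign letters by the highest-mean member of each column
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for g in order:
            if g in col:
                letters[g] += letter
    return letters


@dataclass
class ComparisonResult:
    """One-way ANOVA + Tukey HSD for one trait."""

    trait: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    group_stats: pd.DataFrame  # line, mean, sd, n, letters
    alpha: float

    def summary(self) -> str:
        lines = [
            f"trait: {self.trait}",
            f"one-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_stat:.4g}, p = {self.p_value:.4g}",
            "",
            self.group_stats.to_string(index=False),
        ]
        return "\n".join(lines)


def anova_tukey(
    table: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    group_col: str = "line",
    value_col: str = "value",
) -> ComparisonResult:
    """One-way ANOVA on line plus Tukey HSD and a compact letter display.

    ``table`` is a long-format phenotype table (one row per replicate
    measurement) with at least ``group_col``, ``trait`` and
    ``value_col`` columns.  Lines with fewer than 2 replicates are
    excluded with a warning.  Letters are deterministic for a fixed
    input order.
    """
    sub = table[table["trait"] == trait] if "trait" in table.columns else table
    if sub.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    counts = sub.groupby(group_col)[value_col].count()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(f"excluding lines with < 2 replicates: {thin}")
        sub = sub[~sub[group_col].isin(thin)]
    groups = list(dict.fromkeys(sub[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 lines with >= 2 replicates")

    samples = [sub.loc[sub[group_col] == g, value_col].to_numpy(float) for g in groups]
    f_stat, p_value = stats.f_oneway(*samples)
    n_total = sum(len(s) for s in samples)
    df_between, df_within = len(groups) - 1, n_total - len(groups)

    res = pairwise_tukeyhsd(
        sub[value_col].to_numpy(float), sub[group_col].to_numpy(str), alpha=alpha
    )
    tk = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    tk = tk.rename(columns={"p-adj": "p_adj"})
    tk["p_adj"] = np.asarray(res.pvalues, dtype=float)
    tk["reject"] = np.asarray(res.reject, dtype=bool)

    significant = {
        frozenset((str(r.group1), str(r.group2)))
        for r in tk.itertuples()
        if r.reject
    }
    means = {g: float(np.mean(s)) for g, s in zip(groups, samples)}
    letters = compact_letter_display(groups, means, significant)

    group_stats = pd.DataFrame(
        {
            group_col: groups,
            "mean": [means[g] for g in groups],
            "sd": [float(np.std(s, ddof=1)) for s in samples],
            "n": [len(s) for s in samples],
            "letters": [letters[g] for g in groups],
        }
    )
    return ComparisonResult(
        trait=trait,
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p_value),
        tukey=tk,
        letters=letters,
        group_stats=group_stats,
        alpha=alpha,
    )
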