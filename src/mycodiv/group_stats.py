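"""Treatment-comparison tests and environment-taxon correlations.

Kruskal-Wallis H (tie-corrected, chi-square reference) and one-way
ANOVA with a Tukey-HSD compact letter display, plus a Pearson
correlation matrix between soil indicators and taxon abundances.
Groups sharing a letter in the display are not significantly different
under the chosen pairwise rule at the stated alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupTestResult",
    "kruskal_wallis",
    "one_way_anova",
    "CorrelationTable",
    "pearson_matrix",
    "compact_letters",
]


@dataclass
class GroupTestResult:
    statistic: float       # H (Kruskal-Wallis) or F (ANOVA)
    df: tuple              # (between, within) for F; (k-1,) for H
    p_value: float
    letters: dict | None = None  # group -> compact letter string
    test: str = ""


def _split(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    return values, groups, labels


def compact_letters(labels, reject: dict) -> dict:
    """Insertion-algorithm compact letter display.

    ``reject`` maps unordered label pairs (frozenset) to whether the
    pairwise test rejected equality.  Produces letters such that two
    groups share a letter iff their pairwise comparison did NOT reject.
    """
    labels = list(labels)
    # letter sets: each is a set of mutually non-different labels
    columns: list[set] = [set(labels)]
    for a_i, a in enumerate(labels):
        for b in labels[a_i + 1:]:
            if not reject.get(frozenset((a, b)), False):
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                col_a, col_b = col - {b}, col - {a}
                for new in (col_a, col_b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # absorb duplicates, order letters by the best (first) member
    columns = [c for c in columns if c]
    columns.sort(key=lambda c: min(labels.index(x) for x in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        for lab in labels:
            if lab in col:
                out[lab] += alphabet[i % len(alphabet)]
    return out


def kruskal_wallis(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    The letter display uses pairwise two-sample Kruskal-Wallis
    (equivalently Wilcoxon rank-sum) decisions at ``alpha`` without
    multiplicity correction, mirroring common field-trial reporting.
    """
    values, groups, labels = _split(values, groups)
    samples = [values[groups == g] for g in labels]
    h, p = stats.kruskal(*samples)
    reject = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            try:
                _, pp = stats.kruskal(values[groups == a], values[groups == b])
            except ValueError:  # all identical values in the pair
                pp = 1.0
            reject[frozenset((a, b))] = pp < alpha
    letters = compact_letters(labels, reject)
    return GroupTestResult(statistic=float(h), df=(len(labels) - 1,),
                           p_value=float(p), letters=letters,
                           test="kruskal-wallis")


def one_way_anova(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """Classical one-way ANOVA F with a Tukey-HSD letter display."""
    values, groups, labels = _split(values, groups)
    samples = [values[groups == g] for g in labels]
    f, p = stats.f_oneway(*samples)
    n, k = len(values), len(labels)
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    idx_a, idx_b = tk._multicomp.pairindices
    reject = {}
    for a, b, rej in zip(tk.groupsunique[idx_a], tk.groupsunique[idx_b],
                         tk.reject):
        reject[frozenset((a, b))] = bool(rej)
    letters = compact_letters(labels, reject)
    return GroupTestResult(statistic=float(f), df=(k - 1, n - k),
                           p_value=float(p), letters=letters, test="anova")


@dataclass
class CorrelationTable:
    """Pearson r per (row variable, column variable) pair with a
    two-sided significance flag at ``alpha``."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def pearson_matrix(x_table: pd.DataFrame, y_table: pd.DataFrame,
                   alpha: float = 0.05) -> CorrelationTable:
    """All-pairs Pearson correlation between columns of two tables.

    Rows are aligned on index (observations); r = cov(x, y)/(s_x s_y)
    with a two-sided t-test p-value per cell.
    """
    if not x_table.index.equals(y_table.index):
        y_table = y_table.loc[x_table.index]
    r = pd.DataFrame(index=x_table.columns, columns=y_table.columns,
                     dtype=float)
    p = r.copy()
    for xc in x_table.columns:
        for yc in y_table.columns:
            rr, pp = stats.pearsonr(x_table[xc], y_table[yc])
            r.loc[xc, yc] = rr
            p.loc[xc, yc] = pp
    return CorrelationTable(r=r, p=p, significant=p < alpha, alpha=alpha)
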