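"""Cross-population homogeneity testing with the sequential P_ordered correction.

Each mutation class is tested for homogeneity of its share of private
polymorphism across populations using a Pearson chi-square test on a 2 x P
contingency table (focal-class counts vs all-other-class counts per
population; df = P - 1).  Because a profoundly heterogeneous class distorts
the proportions of every other class, raw p-values are not independent; the
P_ordered correction re-tests each class against only the classes less
significant than it: classes are ranked by raw p, the least significant
class keeps its raw p, and the i-th least significant class is re-tested
with the "other" row restricted to the i-1 classes ranked below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_EXPECTED_FLOOR = 5.0


@dataclass
class HomogeneityTest:
    chi2: float
    df: int
    p: float
    testable: bool
    min_expected: float


def homogeneity_test(
    counts_focal: np.ndarray,
    counts_other: np.ndarray,
    expected_floor: float = DEFAULT_EXPECTED_FLOOR,
) -> HomogeneityTest:
    """Pearson chi-square homogeneity test on a 2 x P table.

    No continuity correction is applied, including for 2 x 2 tables.  The
    test is marked untestable when any expected cell falls below
    ``expected_floor`` (classical rule: 5) or a margin is zero.
    """
    focal = np.asarray(counts_focal, dtype=float)
    other = np.asarray(counts_other, dtype=float)
    if focal.shape != other.shape or focal.ndim != 1:
        raise ValueError("focal and other count vectors must be 1-D and same length")
    table = np.vstack([focal, other])
    df = focal.size - 1
    col_totals = table.sum(axis=0)
    row_totals = table.sum(axis=1)
    if np.any(col_totals == 0) or np.any(row_totals == 0):
        return HomogeneityTest(np.nan, df, np.nan, False, 0.0)
    expected = np.outer(row_totals, col_totals) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df))
    min_expected = float(expected.min())
    return HomogeneityTest(chi2, df, p, bool(min_expected >= expected_floor), min_expected)


def _rank_key(label: str):
    context, _, alt = label.partition(">")
    return (context, alt)


def p_ordered_correction(
    count_table: pd.DataFrame,
    p_raw: pd.Series,
    testable: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """Sequential re-testing of ranked classes against less significant ones.

    Returns ``(p_ordered, rank)`` indexed like ``count_table`` columns; rank 1
    is the least significant testable class (which keeps its raw p).
    Untestable classes get rank/p_ordered NaN and are excluded from every
    restricted universe.  Raw-p ties are broken by class lexicographic order.
    """
    universe = [c for c in count_table.columns if testable[c]]
    # least significant first; ties broken lexicographically on (context, alt)
    order = sorted(universe, key=lambda c: (-p_raw[c], _rank_key(c)))
    p_ordered = pd.Series(np.nan, index=count_table.columns, dtype=float)
    rank = pd.Series(np.nan, index=count_table.columns, dtype=float)
    below = np.zeros(len(count_table.index), dtype=float)
    for i, label in enumerate(order, start=1):
        focal = count_table[label].to_numpy(dtype=float)
        rank[label] = i
        if i == 1:
            p_ordered[label] = p_raw[label]
        else:
            test = homogeneity_test(focal, below, expected_floor=0.0)
            p_ordered[label] = test.p
        below += focal
    return p_ordered, rank


def test_all_classes(
    count_table: pd.DataFrame,
    alpha: float = 0.05,
    expected_floor: float = DEFAULT_EXPECTED_FLOOR,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Full heterogeneity analysis of a population x class count table.

    Each class is tested against the pooled counts of all other classes in
    the universe (table columns minus ``exclude``), then the P_ordered
    correction, a Bonferroni threshold over the testable classes, and
    Benjamini-Hochberg q-values are applied.

    Returns a class-indexed DataFrame with per-population counts, chi2, df,
    p_raw, rank, p_ordered, bonferroni_pass and fdr_q.
    """
    table = count_table.drop(columns=list(exclude), errors="ignore")
    totals = table.sum(axis=1).to_numpy(dtype=float)
    rows = {}
    for label in table.columns:
        focal = table[label].to_numpy(dtype=float)
        test = homogeneity_test(focal, totals - focal, expected_floor)
        rows[label] = test
    result = pd.DataFrame(
        {
            "chi2": {c: t.chi2 for c, t in rows.items()},
            "df": {c: t.df for c, t in rows.items()},
            "p_raw": {c: t.p for c, t in rows.items()},
            "testable": {c: t.testable for c, t in rows.items()},
            "min_expected": {c: t.min_expected for c, t in rows.items()},
        }
    )
    for pop in table.index:
        result[f"count_{pop}"] = table.loc[pop]

    p_ordered, rank = p_ordered_correction(table, result["p_raw"], result["testable"])
    result["p_ordered"] = p_ordered
    result["rank"] = rank

    n_testable = int(result["testable"].sum())
    threshold = bonferroni_threshold(n_testable, alpha)
    result["bonferroni_threshold"] = threshold
    result["bonferroni_pass"] = result["p_ordered"] < threshold

    result["fdr_q"] = np.nan
    mask = result["testable"] & result["p_ordered"].notna()
    if mask.any():
        result.loc[mask, "fdr_q"] = bh_adjust(result.loc[mask, "p_ordered"].to_numpy())
    result.index.name = "class"
    return result


def pairwise_tests(
    count_table: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    alpha: float = 0.05,
    expected_floor: float = DEFAULT_EXPECTED_FLOOR,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Heterogeneity analysis restricted to one pair of populations (df = 1).

    The P_ordered ranking is computed within the pairwise analysis itself.
    """
    for pop in (pop_a, pop_b):
        if pop not in count_table.index:
            raise KeyError(f"population {pop!r} not in count table")
    return test_all_classes(
        count_table.loc[[pop_a, pop_b]], alpha=alpha, expected_floor=expected_floor, exclude=exclude
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling family-wise error at alpha."""
    if n_tests <= 0:
        return np.nan
    return alpha / n_tests


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust(p_values, method: str = "bonferroni", alpha: float = 0.05):
    """Multiple-testing adjustment.

    ``bonferroni`` returns the per-test threshold alpha / n; ``bh_fdr``
    returns BH-adjusted p-values.
    """
    p = np.asarray(list(p_values), dtype=float)
    if method == "bonferroni":
        return bonferroni_threshold(p.size, alpha)
    if method == "bh_fdr":
        return bh_adjust(p)
    raise ValueError(f"unknown method {method!r}")
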