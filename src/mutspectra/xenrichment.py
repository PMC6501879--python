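"""X-chromosome enrichment testing against a demography-scaled null.

Fewer polymorphic sites of any class are expected on X than on the
autosomes (smaller effective population size, sampling), even at equal
mutation rates.  The null X polymorphism probability for a focal class m is
therefore p0 = xi * p_A, where p_A is the autosomal polymorphism
probability of m and xi the ratio of X to autosomal polymorphism
probability measured over all classes other than m.  A one-sided test asks
whether the observed number of privately polymorphic m-sites on X exceeds
Binomial(n_X, p0) (or Poisson(n_X * p0) when only the expected count is
known).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .context import ContextCensus, MutationClass

DEFAULT_MIN_OBSERVED = 6  # tests are skipped at 5 or fewer observations on X


class UndefinedXiError(ValueError):
    """Raised when xi cannot be estimated (zero denominator)."""


@dataclass
class XEnrichmentResult:
    mutation_class: MutationClass
    p_autosomal: float
    xi: float
    p0: float
    n_x: int
    observed_x: int
    expected_x: float
    p_value: float | None
    mode: str


def estimate_xi(
    count_table_aut: pd.DataFrame,
    count_table_x: pd.DataFrame,
    census: ContextCensus,
    population: str,
    exclude_class: MutationClass | str | None = None,
) -> float:
    """Ratio of X to autosomal polymorphism probability over all other classes.

    Counts of the focal class are excluded from both numerators; the census
    denominators are the full per-partition site totals (a single class's
    context is a negligible share of the censused genome).
    """
    label = None
    if exclude_class is not None:
        label = exclude_class if isinstance(exclude_class, str) else exclude_class.label
    aut = count_table_aut.loc[population]
    x = count_table_x.loc[population]
    aut_count = float(aut.sum()) - (float(aut.get(label, 0)) if label else 0.0)
    x_count = float(x.sum()) - (float(x.get(label, 0)) if label else 0.0)
    aut_sites = census.total("autosomes")
    x_sites = census.total("X")
    if aut_sites == 0 or x_sites == 0 or aut_count == 0:
        raise UndefinedXiError("cannot estimate xi: zero autosomal or X denominator")
    return (x_count / x_sites) / (aut_count / aut_sites)


def x_enrichment_test(
    n_x: int,
    observed_x: int,
    p0: float,
    mode: str = "binomial",
) -> float:
    """One-sided upper-tail p-value for the X polymorphism count.

    ``binomial`` computes P(X >= observed) under Binomial(n_x, p0);
    ``poisson`` under Poisson(n_x * p0), which needs only the expected
    count.  At observed_x = 0 the upper tail is 1 by construction.
    """
    if mode == "binomial":
        if observed_x > n_x:
            raise ValueError("observed count exceeds the number of X sites")
        return float(stats.binomtest(observed_x, n_x, p0, alternative="greater").pvalue)
    if mode == "poisson":
        return float(stats.poisson.sf(observed_x - 1, n_x * p0))
    raise ValueError(f"unknown mode {mode!r}")


def x_enrichment_analysis(
    count_table_aut: pd.DataFrame,
    count_table_x: pd.DataFrame,
    census: ContextCensus,
    population: str,
    classes=None,
    mode: str = "binomial",
    min_observed: int = DEFAULT_MIN_OBSERVED,
) -> pd.DataFrame:
    """Per-class X-enrichment tests for one population.

    Classes with fewer than ``min_observed`` private polymorphisms on X are
    reported with a null p-value (test skipped).  ``classes`` defaults to
    every class in the count tables.
    """
    labels = list(classes) if classes is not None else list(count_table_aut.columns)
    labels = [m.label if isinstance(m, MutationClass) else m for m in labels]
    rows = []
    for label in labels:
        m = MutationClass.from_label(label)
        xi = estimate_xi(count_table_aut, count_table_x, census, population, exclude_class=label)
        n_aut = census.context_sites(m.context, "autosomes")
        n_x = census.context_sites(m.context, "X")
        if n_aut == 0 or n_x == 0:
            raise UndefinedXiError(f"zero census for context {m.context}")
        p_a = float(count_table_aut.loc[population, label]) / n_aut
        p0 = xi * p_a
        observed = int(count_table_x.loc[population, label])
        expected = n_x * p0
        p_value = (
            x_enrichment_test(n_x, observed, p0, mode=mode) if observed >= min_observed else None
        )
        rows.append(
            {
                "context": m.context,
                "alt": m.alt,
                "n_X": n_x,
                "observed_X": observed,
                "expected_X": expected,
                "xi": xi,
                "p0": p0,
                "p_value": p_value,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)
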