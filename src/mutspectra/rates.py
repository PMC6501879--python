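"""Calibrated private mutation-rate inference.

The probability that a site is privately polymorphic in a population mixes
mutation rate with demography and sampling.  To compare classes across
populations, per-class polymorphism proportions are calibrated to a
genome-wide de novo rate::

    mu_m = mu_total * theta_m / Theta

where ``theta_m`` is the proportion of censused sites with class m's
context that carry a private polymorphism of class m, ``Theta`` the
proportion of all censused sites carrying any private polymorphism, and
``mu_total`` the genome-wide rate per generation per site (default
1.2e-8).  The census-weighted sum of mu_m over classes then equals
mu_total exactly.  95% confidence intervals use the Wald binomial standard
error on theta_m, treating Theta as a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .context import ContextCensus, MutationClass, enumerate_classes

MU_TOTAL_DEFAULT = 1.2e-8


class UndefinedRateError(ValueError):
    """Raised when a rate is undefined (zero census or zero Theta)."""


@dataclass
class RateEstimate:
    """Calibrated private mutation rate for one (population, class) pair."""

    population: str
    mutation_class: MutationClass
    theta: float
    Theta: float
    mu: float
    ci_low: float
    ci_high: float
    mu_total: float
    zero_count: bool = False


def _totals(count_table: pd.DataFrame, census: ContextCensus, partition: str):
    total_sites = census.total(partition)
    if total_sites == 0:
        raise UndefinedRateError("census has no sites")
    return total_sites


def infer_rate(
    count_table: pd.DataFrame,
    census: ContextCensus,
    population: str,
    m: MutationClass | str,
    mu_total: float = MU_TOTAL_DEFAULT,
    partition: str = "all",
) -> RateEstimate:
    """Estimate the calibrated private mutation rate of class ``m``.

    ``count_table`` must be a population x class table at m's width, built
    on the same chromosome partition as the census is queried with.
    Classes with zero observed count get mu = 0 and a rule-of-three upper
    bound (3/n on theta), flagged via ``zero_count``.
    """
    if isinstance(m, str):
        m = MutationClass.from_label(m)
    n_context = census.context_sites(m.context, partition)
    if n_context == 0:
        raise UndefinedRateError(f"zero census for context {m.context}")
    total_sites = _totals(count_table, census, partition)
    count = int(count_table.loc[population, m.label])
    total_variants = int(count_table.loc[population].sum())
    Theta = total_variants / total_sites
    if Theta == 0:
        raise UndefinedRateError(f"population {population} has no private variants")
    theta = count / n_context
    scale = mu_total / Theta
    mu = scale * theta
    if count == 0:
        return RateEstimate(
            population, m, theta, Theta, 0.0, 0.0, scale * 3.0 / n_context, mu_total, True
        )
    se = np.sqrt(theta * (1.0 - theta) / n_context)
    ci_low = max(0.0, scale * (theta - 1.96 * se))
    ci_high = scale * (theta + 1.96 * se)
    return RateEstimate(population, m, theta, Theta, mu, ci_low, ci_high, mu_total)


def rates_table(
    count_table: pd.DataFrame,
    census: ContextCensus,
    mu_total: float = MU_TOTAL_DEFAULT,
    partition: str = "all",
) -> pd.DataFrame:
    """Per-(population, class) rate estimates as a long DataFrame."""
    rows = []
    for population in count_table.index:
        for label in count_table.columns:
            est = infer_rate(count_table, census, population, label, mu_total, partition)
            m = est.mutation_class
            rows.append(
                {
                    "population": population,
                    "k": m.k,
                    "context": m.context,
                    "alt": m.alt,
                    "theta": est.theta,
                    "mu": est.mu,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    return pd.DataFrame(rows)


def build_signature_matrix(
    count_table: pd.DataFrame,
    census: ContextCensus,
    mu_total: float = MU_TOTAL_DEFAULT,
    partition: str = "all",
) -> pd.DataFrame:
    """Matrix of mu_m with classes as rows and populations as columns.

    Row order follows the canonical class enumeration.  Populations with no
    private variants are dropped with a warning.
    """
    if len(count_table.index) < 2:
        raise ValueError("signature matrix requires at least 2 populations")
    pops = []
    for population in count_table.index:
        if count_table.loc[population].sum() == 0:
            warnings.warn(f"population {population!r} has no private variants; column dropped")
        else:
            pops.append(population)
    k = len(count_table.columns[0].partition(">")[0])
    present = set(count_table.columns)
    labels = [m.label for m in enumerate_classes(k) if m.label in present]
    table = count_table[labels]

    total_sites = census.total(partition)
    context_sites = np.array(
        [census.context_sites(lbl.partition(">")[0], partition) for lbl in labels], dtype=float
    )
    if np.any(context_sites == 0):
        raise UndefinedRateError("zero census for at least one context")
    data = {}
    for population in pops:
        counts = table.loc[population].to_numpy(dtype=float)
        Theta = counts.sum() / total_sites
        data[population] = (MU_TOTAL_DEFAULT if mu_total is None else mu_total) / Theta * (
            counts / context_sites
        )
    return pd.DataFrame(data, index=labels)


def relative_rates(signature_matrix: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-class rates normalized to a reference population (its column = 1)."""
    if reference not in signature_matrix.columns:
        raise KeyError(f"reference population {reference!r} not in matrix")
    ref = signature_matrix[reference]
    if (ref == 0).any():
        raise UndefinedRateError("reference population has zero rate for some class")
    return signature_matrix.div(ref, axis=0)
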