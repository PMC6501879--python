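"""Derived-allele-frequency binning and per-class enrichment spectra.

Variants are binned by DAF using empirical 5% quantiles, collapsing
duplicate quantile values (DAF is discrete in a finite sample, so low-
frequency quantiles often coincide).  Within each bin, a class's enrichment
is its share of the bin's variants divided by its share of all variants;
the bin-size-weighted mean enrichment is therefore exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import is_x_chromosome
from .filtering import VariantRecord


def compute_daf(record: VariantRecord, sub_to_cont=None) -> float | None:
    """Derived allele frequency of a private variant, or None if excluded.

    The DAF is the frequency of the non-ancestral allele among the private
    population's sampled alleles.  Variants are excluded when the ancestral
    call is missing or low-confidence, matches neither allele, or the
    variant is on the X chromosome.
    """
    if record.is_x:
        return None
    if record.ancestral is None or not record.ancestral_high_conf:
        return None
    if record.population is None:
        raise ValueError("record has no private population assigned")
    if sub_to_cont is not None:
        ac = sum(
            a for s, a in record.subpop_ac.items() if sub_to_cont.get(s) == record.population
        )
        an = sum(
            a for s, a in record.subpop_an.items() if sub_to_cont.get(s) == record.population
        )
    else:
        ac, an = record.total_ac(), record.total_an()
    if an == 0:
        return None
    alt_freq = ac / an
    if record.ancestral == record.ref:
        return alt_freq
    if record.ancestral == record.alt:
        return 1.0 - alt_freq
    return None


@dataclass
class DafBinning:
    """Quantile bin edges and per-variant bin assignment for one population.

    Bins are left-open/right-closed on the collapsed quantile edges, with
    the lowest edge inclusive; ties at an edge fall in the lower bin.
    """

    edges: np.ndarray
    bin_index: np.ndarray
    step: float

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bin_index, minlength=self.n_bins)


def bin_by_quantiles(dafs: np.ndarray, step: float = 0.05) -> DafBinning:
    """Bin DAFs at empirical quantiles spaced by ``step``, collapsing duplicates.

    Quantiles use the inverse-CDF (type 1) definition for platform-stable
    reproducibility.  Returns an empty binning for empty input.
    """
    dafs = np.asarray(dafs, dtype=float)
    if dafs.size == 0:
        return DafBinning(np.array([]), np.array([], dtype=int), step)
    probs = np.arange(0.0, 1.0 + step / 2, step)
    edges = np.unique(np.quantile(dafs, probs, method="inverted_cdf"))
    if len(edges) == 1:  # all mass at a single value: one degenerate bin
        return DafBinning(np.array([edges[0], edges[0]]), np.zeros(dafs.size, dtype=int), step)
    # (edges[i], edges[i+1]] with the lowest edge inclusive
    idx = np.searchsorted(edges[1:-1], dafs, side="left")
    return DafBinning(edges, idx.astype(int), step)


def enrichment_by_bin(binning: DafBinning, class_labels) -> pd.DataFrame:
    """Per-bin enrichment of each class (long format).

    enrichment(bin, m) = (share of bin's variants of class m) /
    (share of all variants of class m).  Classes absent overall get NaN.
    """
    labels = pd.Series(np.asarray(class_labels, dtype=object))
    if len(labels) != len(binning.bin_index):
        raise ValueError("class_labels must align with the binned variants")
    if binning.n_bins == 0:
        return pd.DataFrame(
            columns=["bin_index", "bin_low", "bin_high", "bin_n", "class", "enrichment"]
        )
    total = len(labels)
    bin_sizes = binning.bin_sizes()
    overall = labels.value_counts()
    rows = []
    table = pd.crosstab(binning.bin_index, labels)
    table = table.reindex(index=range(binning.n_bins), fill_value=0)
    for label in overall.index.tolist():
        class_total = overall[label]
        for b in range(binning.n_bins):
            n_b = bin_sizes[b]
            in_bin = table.loc[b, label] if label in table.columns else 0
            if n_b == 0 or class_total == 0:
                enr = np.nan
            else:
                enr = (in_bin / n_b) / (class_total / total)
            rows.append(
                {
                    "bin_index": b,
                    "bin_low": binning.edges[b],
                    "bin_high": binning.edges[b + 1],
                    "bin_n": int(n_b),
                    "class": label,
                    "enrichment": enr,
                }
            )
    return pd.DataFrame(rows)


def daf_spectrum(
    records: list[VariantRecord],
    k: int = 3,
    step: float = 0.05,
    sub_to_cont=None,
) -> pd.DataFrame:
    """DAF enrichment spectrum for one population's private variants.

    Computes DAFs (excluding X-chromosome and unpolarizable variants), bins
    them by collapsed 5% quantiles, and returns per-bin per-class
    enrichments at context width ``k``.
    """
    attr = {3: "k3", 5: "k5", 7: "k7"}[k]
    dafs, labels = [], []
    for rec in records:
        d = rec.daf if rec.daf is not None else compute_daf(rec, sub_to_cont)
        label = getattr(rec, attr)
        if d is None or label is None:
            continue
        dafs.append(d)
        labels.append(label)
    binning = bin_by_quantiles(np.asarray(dafs), step=step)
    return enrichment_by_bin(binning, labels)
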