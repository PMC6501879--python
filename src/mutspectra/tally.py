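"""Count private variants per folded mutation class, population and partition."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .context import enumerate_classes
from .filtering import PrivateVariantSet

PARTITIONS = ("all", "autosomes", "X")
_K_ATTR = {3: "k3", 5: "k5", 7: "k7"}


def tally(
    private_sets: Mapping[str, PrivateVariantSet],
    k: int,
    partition: str = "all",
) -> pd.DataFrame:
    """Build a population x class count table at context width ``k``.

    Columns are the full canonical class-label space at width ``k`` in
    enumeration order; rows are populations.  ``partition`` selects
    autosomal variants, X variants, or both.  Variants whose window at
    width ``k`` was unclassifiable (N or sequence edge) are omitted at that
    width, so each width's table has its own row sums.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}")
    attr = _K_ATTR[k]
    labels = [m.label for m in enumerate_classes(k)]
    col_index = {label: i for i, label in enumerate(labels)}
    rows = {}
    for pop, pset in private_sets.items():
        counts = [0] * len(labels)
        for rec in pset.variants:
            if partition == "autosomes" and rec.is_x:
                continue
            if partition == "X" and not rec.is_x:
                continue
            label = getattr(rec, attr)
            if label is not None:
                counts[col_index[label]] += 1
        rows[pop] = counts
    table = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    table.index.name = "population"
    return table


def marginalize(table: pd.DataFrame, k_target: int) -> pd.DataFrame:
    """Collapse a count table to a narrower width by trimming flanks.

    Summing a 7-mer table over the expansions of each 3-mer class
    reproduces the 3-mer table restricted to variants classifiable at the
    wider width.
    """
    from .context import MutationClass

    out: dict[str, list] = {}
    for label in table.columns:
        trimmed = MutationClass.from_label(label).trim(k_target).label
        out.setdefault(trimmed, []).append(label)
    labels = [m.label for m in enumerate_classes(k_target)]
    collapsed = pd.DataFrame(
        {t: table[cols].sum(axis=1) for t, cols in out.items()}
    ).reindex(columns=labels, fill_value=0)
    collapsed.index.name = "population"
    return collapsed


def to_long(tables: Mapping[tuple[int, str], pd.DataFrame]) -> pd.DataFrame:
    """Long-format view of count tables keyed by (k, partition)."""
    frames = []
    for (k, partition), table in tables.items():
        long = table.reset_index().melt(
            id_vars="population", var_name="class", value_name="count"
        )
        long["k"] = k
        long["partition"] = partition
        long["context"] = long["class"].str.partition(">")[0]
        long["alt"] = long["class"].str.partition(">")[2]
        frames.append(long[["population", "k", "context", "alt", "partition", "count"]])
    return pd.concat(frames, ignore_index=True)
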