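"""Normalization and hierarchical clustering of mutation-rate signatures.

The "signature" of a class is its vector of calibrated rates across
populations.  Each vector is normalized to log2 fold difference over its
own mean, so a constant vector maps to zeros and the transform is invariant
to rescaling a whole class.  Classes are then clustered with Euclidean
distance and (by default) complete linkage; cutting the dendrogram groups
classes with shared patterns of enrichment/depletion across populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def normalize(signature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise mean-fold log2 transform of a class x population rate matrix.

    Rows containing a zero (or negative) rate cannot be log-normalized and
    are dropped with a warning.
    """
    values = signature_matrix.to_numpy(dtype=float)
    ok = (values > 0).all(axis=1)
    if not ok.all():
        dropped = signature_matrix.index[~ok].tolist()
        warnings.warn(f"dropping {len(dropped)} row(s) with nonpositive rates: {dropped[:5]}")
    kept = signature_matrix.loc[ok]
    values = kept.to_numpy(dtype=float)
    folds = values / values.mean(axis=1, keepdims=True)
    return pd.DataFrame(np.log2(folds), index=kept.index, columns=kept.columns)


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: pd.Series           # flat cluster id per class (when a cut was requested)
    leaf_order: list[str]
    newick: str


def cluster(
    normalized: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> ClusteringResult:
    """Hierarchically cluster normalized signature rows.

    Returns the linkage matrix, flat cluster labels at the requested cut
    (``n_clusters`` or ``height``; otherwise all rows in one cluster), the
    dendrogram leaf order, and a Newick serialization.  Deterministic given
    the input row order; identical rows merge at height 0.
    """
    if normalized.shape[0] < 2:
        raise ValueError("clustering requires at least 2 rows")
    Z = hierarchy.linkage(normalized.to_numpy(dtype=float), method=linkage, metric=metric)
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        flat = np.ones(normalized.shape[0], dtype=int)
    leaves = hierarchy.leaves_list(Z)
    names = list(normalized.index)
    return ClusteringResult(
        linkage=Z,
        labels=pd.Series(flat, index=normalized.index, name="cluster"),
        leaf_order=[names[i] for i in leaves],
        newick=to_newick(Z, names),
    )


def to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree string.

    Branch lengths are differences in merge height, as is conventional for
    ultrametric dendrograms.
    """
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{_escape(names[node.id])}:{length:g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:g}"

    inner = f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"
    return inner


def _escape(name: str) -> str:
    if any(c in name for c in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name
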