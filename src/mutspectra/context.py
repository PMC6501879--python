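"""Folded k-mer mutation classes and genomic context censusing.

A mutation class is a reference sequence context of odd width k (3, 5 or 7)
together with the alternate allele at the central position.  Because a
polymorphism is strand-symmetric, each class is identified with its
reverse complement (e.g. ``TCC>T`` and ``GGA>A`` are the same class); the
canonical representative is the strand on which the central reference base
is A or C.  This yields 96 classes at k=3, 1,536 at k=5 and 24,576 at k=7.

The context census counts, for every canonical context string, the number
of genomic positions whose folded surrounding sequence equals it.  These
counts are the denominators of per-class polymorphism probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUPPORTED_K = (3, 5, 7)


class InvalidClassError(ValueError):
    """Raised for malformed (context, alt) inputs."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_x_chromosome(name: str) -> bool:
    """True for sequence names that denote the X chromosome (X, chrX, ...)."""
    stem = name.lower()
    if stem.startswith("chr"):
        stem = stem[3:]
    return stem == "x"


@dataclass(frozen=True, order=True)
class MutationClass:
    """A canonical (folded) mutation class.

    ``context`` is the reference k-mer on the canonical strand (central base
    A or C) and ``alt`` the alternate allele at the central position.
    """

    context: str
    alt: str

    def __post_init__(self) -> None:
        k = len(self.context)
        if k % 2 == 0 or k < 3:
            raise InvalidClassError(f"context width must be odd and >=3, got {k}")
        if any(b not in BASES for b in self.context) or self.alt not in BASES:
            raise InvalidClassError(
                f"non-ACGT base in class {self.context}>{self.alt}"
            )
        if self.central not in "AC":
            raise InvalidClassError(
                f"class {self.context}>{self.alt} is not canonical "
                "(central base must be A or C; use fold())"
            )
        if self.alt == self.central:
            raise InvalidClassError(
                f"alt equals the reference central base in {self.context}>{self.alt}"
            )

    @property
    def k(self) -> int:
        return len(self.context)

    @property
    def central(self) -> str:
        return self.context[len(self.context) // 2]

    @property
    def label(self) -> str:
        return f"{self.context}>{self.alt}"

    def trim(self, k: int) -> "MutationClass":
        """Central k-mer sub-class (e.g. the 3-mer class of a 7-mer class)."""
        if k > self.k or k % 2 == 0:
            raise InvalidClassError(f"cannot trim width-{self.k} class to k={k}")
        f = (self.k - k) // 2
        return MutationClass(self.context[f : self.k - f], self.alt)

    @classmethod
    def from_label(cls, label: str) -> "MutationClass":
        context, _, alt = label.partition(">")
        return cls(context, alt)


def fold(context: str, alt: str) -> MutationClass:
    """Fold a (context, alt) pair onto its canonical strand.

    The pair and its reverse complement name the same polymorphism class;
    the canonical representative has central reference base A or C.
    """
    context = context.upper()
    alt = alt.upper()
    k = len(context)
    if k % 2 == 0:
        raise InvalidClassError(f"context width must be odd, got {k}")
    if any(b not in BASES for b in context) or alt not in BASES:
        raise InvalidClassError(f"non-ACGT base in ({context}, {alt})")
    central = context[k // 2]
    if alt == central:
        raise InvalidClassError(f"alt {alt} equals the reference central base")
    if central in "AC":
        return MutationClass(context, alt)
    return MutationClass(reverse_complement(context), alt.translate(_COMPLEMENT))


def fold_context(context: str) -> str:
    """Canonical representative of a context string alone (central base A/C)."""
    context = context.upper()
    central = context[len(context) // 2]
    if central in "AC":
        return context
    return reverse_complement(context)


def _check_k(k: int) -> None:
    if k not in SUPPORTED_K:
        raise InvalidClassError(f"unsupported context width k={k}; must be one of {SUPPORTED_K}")


@lru_cache(maxsize=None)
def _enumerate_classes_cached(k: int) -> tuple[MutationClass, ...]:
    flank = k // 2
    out = []
    for left in product(BASES, repeat=flank):
        for central in "AC":
            for right in product(BASES, repeat=flank):
                ctx = "".join(left) + central + "".join(right)
                for alt in BASES:
                    if alt != central:
                        out.append(MutationClass(ctx, alt))
    out.sort()
    return tuple(out)


def enumerate_classes(k: int) -> list[MutationClass]:
    """All canonical mutation classes of width k, in lexicographic order.

    Lengths are 96, 1,536 and 24,576 for k = 3, 5 and 7.
    """
    _check_k(k)
    return list(_enumerate_classes_cached(k))


def expansions(class3: MutationClass, k_target: int) -> list[MutationClass]:
    """All width-``k_target`` classes whose central trinucleotide folds to ``class3``.

    Each 3-mer class expands into 16**((k_target-3)/2) wider classes
    (256 at k=7).
    """
    if class3.k != 3:
        raise InvalidClassError("expansions requires a 3-mer class")
    _check_k(k_target)
    flank = (k_target - 3) // 2
    if flank == 0:
        return [class3]
    out = [
        MutationClass("".join(left) + class3.context + "".join(right), class3.alt)
        for left in product(BASES, repeat=flank)
        for right in product(BASES, repeat=flank)
    ]
    out.sort()
    return out


# --------------------------------------------------------------------------
# context census
# --------------------------------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


@lru_cache(maxsize=None)
def _canonical_index_map(k: int) -> np.ndarray:
    """Map every raw k-mer index to the index of its folded representative."""
    n = 4**k
    idx = np.arange(n, dtype=np.int64)
    digits = np.empty((k, n), dtype=np.int64)
    t = idx.copy()
    for j in range(k - 1, -1, -1):
        digits[j] = t % 4
        t //= 4
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        rc += (3 - digits[j]) * 4**j
    central = digits[k // 2]
    return np.where(central <= 1, idx, rc)


@lru_cache(maxsize=None)
def _index_to_context(k: int) -> np.ndarray:
    n = 4**k
    out = np.empty(n, dtype=object)
    for i in range(n):
        t, chars = i, []
        for _ in range(k):
            chars.append(BASES[t % 4])
            t //= 4
        out[i] = "".join(reversed(chars))
    return out


def canonical_contexts(k: int) -> list[str]:
    """All canonical context strings of width k (central base A or C), sorted."""
    _check_k(k)
    cmap = _canonical_index_map(k)
    ctx = _index_to_context(k)
    return sorted(ctx[np.unique(cmap)])


def _encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw k-mer index per window start, plus validity (no non-ACGT base)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j : j + n]
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return idx, valid


@dataclass
class ContextCensus:
    """Per-context counts of eligible genomic sites, split autosomes vs X.

    ``counts`` is indexed by canonical context string with integer columns
    ``autosomes`` and ``X``.
    """

    k: int
    counts: pd.DataFrame

    PARTITIONS = ("autosomes", "X", "all")

    def _column(self, partition: str) -> pd.Series:
        if partition == "all":
            return self.counts["autosomes"] + self.counts["X"]
        if partition not in ("autosomes", "X"):
            raise ValueError(f"unknown partition {partition!r}")
        return self.counts[partition]

    def total(self, partition: str = "all") -> int:
        """Total censused sites in a partition."""
        return int(self._column(partition).sum())

    def context_sites(self, context: str, partition: str = "all") -> int:
        """Number of censused sites whose folded context equals ``context``."""
        col = self._column(partition)
        return int(col.get(fold_context(context), 0))

    def to_tsv(self, path, meta: Mapping[str, str] | None = None) -> None:
        from . import _io

        df = self.counts.reset_index().rename(
            columns={"index": "context", "autosomes": "autosome_count", "X": "x_count"}
        )
        _io.write_tsv(df, path, meta={"k": str(self.k), **(meta or {})})

    @classmethod
    def from_tsv(cls, path) -> "ContextCensus":
        from . import _io

        df = _io.read_tsv(path)
        k = len(df["context"].iloc[0])
        counts = pd.DataFrame(
            {
                "autosomes": df["autosome_count"].to_numpy(),
                "X": df["x_count"].to_numpy(),
            },
            index=df["context"],
        )
        counts.index.name = None
        return cls(k=k, counts=counts)


def _as_sequences(genome) -> Iterable[tuple[str, str]]:
    """Yield (name, uppercase sequence) from a dict or pyfaidx.Fasta-like."""
    if isinstance(genome, Mapping):
        items = genome.items()
    else:  # pyfaidx.Fasta exposes keys() and string-able records
        items = ((name, str(genome[name])) for name in genome.keys())
    for name, seq in items:
        yield name, str(seq).upper()


def census(genome, k: int, exclusion_mask=None) -> ContextCensus:
    """Tabulate folded k-mer contexts over all eligible genomic positions.

    A position is eligible when it is outside the exclusion mask and its
    k-window contains no non-ACGT base.  Soft-masked (lowercase) bases are
    uppercased; exclusion is governed solely by the mask.  Positions on
    X-named sequences accumulate in the X partition.

    Parameters
    ----------
    genome
        Mapping of sequence name to sequence, or a pyfaidx.Fasta.
    k
        Context width, one of 3/5/7.
    exclusion_mask
        Mapping chrom -> iterable of (start, end) 0-based half-open
        intervals to exclude, or None.
    """
    _check_k(k)
    cmap = _canonical_index_map(k)
    counts = {"autosomes": np.zeros(4**k, dtype=np.int64), "X": np.zeros(4**k, dtype=np.int64)}
    flank = k // 2
    mask = dict(exclusion_mask) if exclusion_mask else {}
    seq_names = set()

    for name, seq in _as_sequences(genome):
        seq_names.add(name)
        codes = _encode_sequence(seq)
        idx, valid = _kmer_indices(codes, k)
        if idx.size == 0:
            continue
        if name in mask:
            keep = np.ones(len(seq), dtype=bool)
            for start, end in mask[name]:
                keep[max(0, int(start)) : max(0, int(end))] = False
            valid = valid & keep[flank : flank + idx.size]
        part = "X" if is_x_chromosome(name) else "autosomes"
        counts[part] += np.bincount(cmap[idx[valid]], minlength=4**k)

    for chrom in mask:
        if chrom not in seq_names:
            warnings.warn(f"mask interval(s) on absent sequence {chrom!r} skipped")

    ctx_strings = _index_to_context(k)
    canonical = np.unique(cmap)
    frame = pd.DataFrame(
        {
            "autosomes": counts["autosomes"][canonical],
            "X": counts["X"][canonical],
        },
        index=pd.Index(ctx_strings[canonical]),
    ).sort_index()
    return ContextCensus(k=k, counts=frame)
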