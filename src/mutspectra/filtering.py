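"""Variant ingestion, filtering, private-set construction and classification.

A variant is "private" to a continental group when its alternate allele is
observed (allele count > 0) in that group and in none of the other groups.
Continent-private variants are propagated to every subpopulation in which
the alternate allele is observed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .context import BASES, MutationClass, fold, is_x_chromosome

logger = logging.getLogger(__name__)


class RefMismatchError(ValueError):
    """Reference allele in a record disagrees with the reference genome."""


@dataclass
class VariantRecord:
    """One variant call with per-subpopulation allele counts.

    ``pos`` is 0-based (converted from the 1-based VCF coordinate on ingest).
    Classification fields (``k3``/``k5``/``k7`` class labels, ``daf``,
    ``population``) are filled by later pipeline stages.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_tag: str
    subpop_ac: dict[str, int]
    subpop_an: dict[str, int]
    ancestral: str | None = None
    ancestral_high_conf: bool = False
    is_snv: bool = True
    is_biallelic: bool = True
    k3: str | None = None
    k5: str | None = None
    k7: str | None = None
    daf: float | None = None
    population: str | None = None

    @property
    def is_x(self) -> bool:
        return is_x_chromosome(self.chrom)

    def total_ac(self) -> int:
        return sum(self.subpop_ac.values())

    def total_an(self) -> int:
        return sum(self.subpop_an.values())

    def minor_allele_count(self) -> int:
        ac, an = self.total_ac(), self.total_an()
        return min(ac, an - ac)

    def group_ac(self, sub_to_cont: Mapping[str, str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for sub, ac in self.subpop_ac.items():
            cont = sub_to_cont.get(sub)
            if cont is not None:
                out[cont] = out.get(cont, 0) + ac
        return out

    def group_an(self, sub_to_cont: Mapping[str, str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for sub, an in self.subpop_an.items():
            cont = sub_to_cont.get(sub)
            if cont is not None:
                out[cont] = out.get(cont, 0) + an
        return out


@dataclass
class PrivateVariantSet:
    """Variants private to one population, with their context classes and DAF."""

    population: str
    variants: list[VariantRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "k3_class": v.k3,
                "k5_class": v.k5,
                "k7_class": v.k7,
                "daf": v.daf,
            }
            for v in self.variants
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "k3_class", "k5_class", "k7_class", "daf"]
        )


def read_vcf(path, manifest: pd.DataFrame) -> list[VariantRecord]:
    """Read a VCF into VariantRecords with per-subpopulation allele counts.

    Counts come from ``AC_<subpop>``/``AN_<subpop>`` INFO fields when present,
    otherwise from GT genotypes via the sample manifest.  Multiallelic and
    non-SNV records are retained (flagged) so that filtering can count them.
    Records that cannot be parsed are logged and skipped.
    """
    import pysam

    from ._io import manifest_maps

    sub_to_cont, _ = manifest_maps(manifest)
    subpops = list(sub_to_cont)
    sample_to_sub = dict(zip(manifest["sample"], manifest["subpopulation"]))

    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        has_info_counts = all(f"AC_{sub}" in vf.header.info for sub in subpops)
        for rec in vf:
            try:
                records.append(
                    _parse_record(rec, subpops, sample_to_sub, has_info_counts)
                )
            except Exception as exc:  # malformed record: log and continue
                skipped += 1
                logger.warning("skipping malformed record %s:%s (%s)", rec.chrom, rec.pos, exc)
    if skipped:
        logger.warning("skipped %d malformed records", skipped)
    return records


def _parse_record(rec, subpops, sample_to_sub, has_info_counts) -> VariantRecord:
    alts = rec.alts or ()
    is_biallelic = len(alts) == 1
    alt = alts[0] if alts else ""
    is_snv = (
        is_biallelic
        and len(rec.ref) == 1
        and len(alt) == 1
        and rec.ref in BASES
        and alt in BASES
    )
    filters = list(rec.filter.keys())
    filter_tag = filters[0] if filters else "PASS"

    if has_info_counts:
        subpop_ac = {s: int(_scalar(rec.info.get(f"AC_{s}", 0))) for s in subpops}
        subpop_an = {s: int(_scalar(rec.info.get(f"AN_{s}", 0))) for s in subpops}
    else:
        subpop_ac = {s: 0 for s in subpops}
        subpop_an = {s: 0 for s in subpops}
        for sample, call in rec.samples.items():
            sub = sample_to_sub.get(sample)
            if sub is None:
                continue
            for allele in call.allele_indices or ():
                if allele is None:
                    continue
                subpop_an[sub] += 1
                if allele >= 1:
                    subpop_ac[sub] += 1

    aa = rec.info.get("AA")
    if isinstance(aa, tuple):
        aa = aa[0]
    ancestral = None
    high_conf = False
    if aa:
        aa = str(aa).split("|")[0]
        if aa.upper() in BASES:
            ancestral = aa.upper()
            high_conf = aa in BASES  # lowercase = low-confidence call
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos - 1,
        ref=rec.ref,
        alt=alt,
        filter_tag=filter_tag,
        subpop_ac=subpop_ac,
        subpop_an=subpop_an,
        ancestral=ancestral,
        ancestral_high_conf=high_conf,
        is_snv=is_snv,
        is_biallelic=is_biallelic,
    )


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def _in_mask(record: VariantRecord, mask: Mapping[str, Sequence[tuple[int, int]]]) -> bool:
    for start, end in mask.get(record.chrom, ()):
        if start <= record.pos < end:
            return True
    return False


@dataclass
class FilterStats:
    """Counts of records removed by each filter."""

    input: int = 0
    not_snv: int = 0
    not_pass: int = 0
    masked: int = 0
    low_mac: int = 0
    high_missingness: int = 0
    passed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def filter_variants(
    records: Iterable[VariantRecord],
    mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    mac_min: int = 2,
    missingness: float | None = None,
    subpop_sizes: Mapping[str, int] | None = None,
) -> tuple[list[VariantRecord], FilterStats]:
    """Apply the standard variant filters.

    Survivors are biallelic SNVs with a PASS filter tag, outside the
    exclusion mask, with minor allele count across all samples >= ``mac_min``.
    When ``missingness`` is set (fraction, e.g. 0.2), records with more than
    that fraction of missing alleles in any subpopulation are also removed
    (requires ``subpop_sizes``).  Filters commute, so application order is
    immaterial.
    """
    stats = FilterStats()
    out: list[VariantRecord] = []
    for rec in records:
        stats.input += 1
        if not (rec.is_snv and rec.is_biallelic):
            stats.not_snv += 1
            continue
        if rec.filter_tag != "PASS":
            stats.not_pass += 1
            continue
        if mask and _in_mask(rec, mask):
            stats.masked += 1
            continue
        if rec.minor_allele_count() < mac_min:
            stats.low_mac += 1
            continue
        if missingness is not None:
            if subpop_sizes is None:
                raise ValueError("missingness filter requires subpop_sizes")
            missing = False
            for sub, n in subpop_sizes.items():
                expected = 2 * n
                if expected and (expected - rec.subpop_an.get(sub, 0)) / expected > missingness:
                    missing = True
                    break
            if missing:
                stats.high_missingness += 1
                continue
        out.append(rec)
        stats.passed += 1
    return out, stats


def extract_private(
    records: Iterable[VariantRecord],
    groups: Sequence[str],
    sub_to_cont: Mapping[str, str],
    provenance: Mapping | None = None,
) -> dict[str, PrivateVariantSet]:
    """Partition filtered variants into per-group private sets.

    A variant is private to a group when its alternate allele count is
    positive in that group and zero in every other group; variants observed
    in two or more groups are discarded.  The returned sets are pairwise
    disjoint by construction.
    """
    groups = list(groups)
    represented = set(sub_to_cont.values())
    for g in groups:
        if g not in represented:
            raise ValueError(f"group {g!r} has no subpopulations in the manifest")
    sets = {g: PrivateVariantSet(g, [], dict(provenance or {})) for g in groups}
    for rec in records:
        gac = rec.group_ac(sub_to_cont)
        observed = [g for g in groups if gac.get(g, 0) > 0]
        if len(observed) == 1:
            rec.population = observed[0]
            sets[observed[0]].variants.append(rec)
    return sets


def propagate_to_subpopulations(
    private_sets: Mapping[str, PrivateVariantSet],
    sub_to_cont: Mapping[str, str],
) -> dict[str, PrivateVariantSet]:
    """Pass continent-private variants to every subpopulation observing them.

    A variant private to a continent joins the list of each of that
    continent's subpopulations where its alternate allele count is positive;
    the union of a continent's subpopulation lists equals its private set.
    """
    cont_to_subs: dict[str, list[str]] = {}
    for sub, cont in sub_to_cont.items():
        cont_to_subs.setdefault(cont, []).append(sub)
    for cont in private_sets:
        if cont not in cont_to_subs:
            raise ValueError(f"no subpopulations assigned to continent {cont!r}")
    out: dict[str, PrivateVariantSet] = {}
    for cont, pset in private_sets.items():
        for sub in cont_to_subs[cont]:
            out[sub] = PrivateVariantSet(sub, [], dict(pset.provenance))
        for rec in pset.variants:
            for sub in cont_to_subs[cont]:
                if rec.subpop_ac.get(sub, 0) > 0:
                    out[sub].variants.append(rec)
    return out


def classify_variant(record: VariantRecord, genome: Mapping[str, str]) -> VariantRecord:
    """Assign folded 3/5/7-mer class labels to a variant in place.

    The window at each width must lie inside the sequence and contain no
    non-ACGT base; otherwise that width (and any wider one) is left
    unclassified.  Raises :class:`RefMismatchError` when the genome base at
    the site differs from the record's reference allele.
    """
    seq = genome[record.chrom]
    base = seq[record.pos].upper()
    if base != record.ref:
        raise RefMismatchError(
            f"{record.chrom}:{record.pos + 1}: reference genome has {base}, record has {record.ref}"
        )
    for k, attr in ((3, "k3"), (5, "k5"), (7, "k7")):
        flank = k // 2
        lo, hi = record.pos - flank, record.pos + flank + 1
        if lo < 0 or hi > len(seq):
            setattr(record, attr, None)
            continue
        window = seq[lo:hi].upper()
        if any(b not in BASES for b in window):
            setattr(record, attr, None)
            continue
        setattr(record, attr, fold(window, record.alt).label)
    return record


def classify_all(
    private_sets: Mapping[str, PrivateVariantSet], genome: Mapping[str, str]
) -> None:
    """Classify every variant in every private set (in place)."""
    for pset in private_sets.values():
        for rec in pset.variants:
            classify_variant(rec, genome)
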