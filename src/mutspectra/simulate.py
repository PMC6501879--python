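"""Synthetic genomes and private variant sets with known, planted parameters.

The generator emulates the statistical structure the analysis consumes: a
random reference genome with named autosomes and one X chromosome; four
continental groups (with 1000-Genomes-like subpopulation structure and
sample sizes) whose private variant sets are disjoint by construction; per
3-mer-class polymorphism probabilities with configurable planted fold
enrichments per population; a reduced X-chromosome baseline (ratio
``xi_true``); and derived allele frequencies drawn from a neutral-like
1/i site frequency spectrum with minor allele count >= 2 enforced.

Privacy is generated structurally (each eligible site becomes a private
variant of at most one population), not via a demographic model: the
downstream statistics consume private sets, and coalescent realism is
orthogonal to validating them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context import (
    BASES,
    ContextCensus,
    MutationClass,
    _canonical_index_map,
    _encode_sequence,
    _index_to_context,
    _kmer_indices,
    canonical_contexts,
    enumerate_classes,
    is_x_chromosome,
)
from .filtering import VariantRecord

_COMP_CODE = np.array([3, 2, 1, 0])

# 1000-Genomes phase 3 non-admixed subpopulation sample sizes
DEFAULT_POPULATIONS: dict[str, dict[str, int]] = {
    "AFR": {"ESN": 99, "GWD": 113, "LWK": 99, "MSL": 85, "YRI": 108},
    "EUR": {"CEU": 99, "FIN": 99, "GBR": 91, "IBS": 107, "TSI": 107},
    "EAS": {"CDX": 93, "CHB": 103, "CHS": 105, "JPT": 104, "KHV": 99},
    "SAS": {"BEB": 86, "GIH": 103, "ITU": 102, "PJL": 96, "STU": 102},
}

# Overall private polymorphism probabilities per group, scaled to the
# observed private-set sizes over the accessible genome (~2.9 Gb):
# 7.0M, 1.2M, 1.96M, 1.99M variants for AFR, EUR, EAS, SAS.
DEFAULT_THETA_TOTAL: dict[str, float] = {
    "AFR": 2.4e-3,
    "EUR": 4.1e-4,
    "EAS": 6.8e-4,
    "SAS": 6.9e-4,
}

DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 1_000_000,
    "chr2": 1_000_000,
    "chr3": 1_000_000,
    "chr4": 1_000_000,
    "chrX": 500_000,
}


@dataclass(frozen=True)
class PlantedEnrichment:
    """Multiply the polymorphism probability of some classes in one population."""

    classes: tuple[str, ...]
    population: str
    fold: float


@dataclass(frozen=True)
class DafPulse:
    """Multiply the SFS weight of one class inside a DAF band."""

    class_label: str
    low: float
    high: float
    fold: float


@dataclass
class SimulationConfig:
    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    populations: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(s) for g, s in DEFAULT_POPULATIONS.items()}
    )
    theta_total: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA_TOTAL))
    theta3: dict[str, dict[str, float]] | None = None  # explicit per-class override
    planted_enrichments: tuple[PlantedEnrichment, ...] = ()
    daf_pulses: tuple[DafPulse, ...] = ()
    xi_true: float = 0.6
    prob_derived_is_ref: float = 0.02
    prob_low_conf_ancestral: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        for enr in self.planted_enrichments:
            if enr.fold <= 0:
                raise ValueError("planted folds must be positive")
        if not (0 < self.xi_true):
            raise ValueError("xi_true must be positive")

    def class_theta(self) -> pd.DataFrame:
        """Per-population, per-class baseline polymorphism probabilities."""
        labels = [m.label for m in enumerate_classes(3)]
        if self.theta3 is not None:
            frame = pd.DataFrame(self.theta3).T.reindex(columns=labels)
            if frame.isna().any().any():
                raise ValueError("theta3 must cover all 96 classes for each population")
            return frame
        # theta_m is a per-context-site probability; with three alternate
        # alleles per context, a uniform spectrum with genome-wide private
        # polymorphism proportion theta_total needs theta_m = theta_total / 3.
        data = {
            pop: np.full(len(labels), total / 3.0)
            for pop, total in self.theta_total.items()
        }
        return pd.DataFrame(data, index=labels).T

    def effective_theta(self) -> pd.DataFrame:
        """Baseline thetas with planted folds applied."""
        theta = self.class_theta().copy()
        for enr in self.planted_enrichments:
            for label in enr.classes:
                theta.loc[enr.population, label] *= enr.fold
        return theta

    def subpop_to_continent(self) -> dict[str, str]:
        return {s: g for g, subs in self.populations.items() for s in subs}

    def manifest(self) -> pd.DataFrame:
        rows = []
        for group, subs in self.populations.items():
            for sub, n in subs.items():
                for i in range(n):
                    rows.append({"sample": f"{sub}{i:04d}", "subpopulation": sub, "continent": group})
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chrom_lengths": self.chrom_lengths,
            "base_composition": list(self.base_composition),
            "populations": self.populations,
            "theta_total": self.theta_total,
            "theta3": self.theta3,
            "planted_enrichments": [vars(e) | {"classes": list(e.classes)} for e in self.planted_enrichments],
            "daf_pulses": [vars(p) for p in self.daf_pulses],
            "xi_true": self.xi_true,
            "prob_derived_is_ref": self.prob_derived_is_ref,
            "prob_low_conf_ancestral": self.prob_low_conf_ancestral,
        }


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one master seed."""
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(seed), child])


def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Draw an i.i.d. random genome with the configured composition."""
    rng = substream(config.seed, "genome")
    base_array = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    out = {}
    for name, length in config.chrom_lengths.items():
        codes = rng.choice(4, size=length, p=np.asarray(config.base_composition))
        out[name] = base_array[codes].tobytes().decode("ascii")
    return out


def sample_derived_counts(
    n: int,
    two_n: int,
    rng: np.random.Generator,
    pulse: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Draw derived allele counts i in [2, 2N-2] with P(i) proportional to 1/i.

    ``pulse`` = (low, high, fold) multiplies the weight of counts whose
    frequency i/2N lies in [low, high].
    """
    counts = np.arange(2, two_n - 1)
    weights = 1.0 / counts
    if pulse is not None:
        low, high, fold = pulse
        freq = counts / two_n
        weights = np.where((freq >= low) & (freq <= high), weights * fold, weights)
    weights /= weights.sum()
    return rng.choice(counts, size=n, p=weights)


def _site_groups(genome: Mapping[str, str]):
    """Per chromosome: central positions with a valid 7-mer window, grouped
    by folded 3-mer context index, plus the strand-flip flag per position."""
    canon3 = _canonical_index_map(3)
    groups = {}
    for name, seq in genome.items():
        codes = _encode_sequence(seq.upper())
        idx7, valid7 = _kmer_indices(codes, 7)
        if idx7.size == 0:
            groups[name] = {}
            continue
        centers = np.arange(3, 3 + idx7.size)
        idx3, _ = _kmer_indices(codes, 3)
        ctx3 = idx3[2 : 2 + idx7.size]  # 3-mer window centered at each 7-mer center
        keep = valid7
        centers, ctx3 = centers[keep], ctx3[keep]
        folded = canon3[ctx3]
        flipped = folded != ctx3
        order = np.argsort(folded, kind="stable")
        folded_sorted = folded[order]
        per_ctx = {}
        uniq = np.unique(folded_sorted)
        starts = np.searchsorted(folded_sorted, uniq, side="left")
        ends = np.searchsorted(folded_sorted, uniq, side="right")
        for u, s, e in zip(uniq, starts, ends):
            sel = order[s:e]
            per_ctx[int(u)] = (centers[sel], flipped[sel])
        groups[name] = per_ctx
    return groups


def simulate_private_variants(
    genome: Mapping[str, str],
    config: SimulationConfig,
) -> tuple[list[VariantRecord], dict]:
    """Scatter private variants over the genome according to planted rates.

    Each eligible site (valid 7-mer window) of folded 3-mer context c
    independently becomes a private variant of population p and class
    (c, alt) with probability theta_m(p) * fold, scaled by ``xi_true`` on
    the X chromosome; at most one (population, alt) event per site, so the
    four private sets are disjoint by construction.  Derived allele counts
    follow the configured SFS with minor allele count >= 2.

    Returns the variant records (sorted) and a truth dictionary of the
    planted parameters.
    """
    theta = config.effective_theta()
    pops = list(theta.index)
    labels3 = list(theta.columns)
    ctx_strings = _index_to_context(3)
    pulses = {p.class_label: (p.low, p.high, p.fold) for p in config.daf_pulses}

    # event table per folded 3-mer context: (pop, alt, label, prob)
    events_by_ctx: dict[int, list[tuple[str, str, str, float]]] = {}
    for ctx in canonical_contexts(3):
        ctx_idx = int(np.where(ctx_strings == ctx)[0][0])
        central = ctx[1]
        events = []
        for pop in pops:
            for alt in BASES:
                if alt == central:
                    continue
                label = f"{ctx}>{alt}"
                events.append((pop, alt, label, float(theta.loc[pop, label])))
        events_by_ctx[ctx_idx] = events

    max_prob = max(sum(e[3] for e in events) for events in events_by_ctx.values())
    if max_prob * max(config.xi_true, 1.0) >= 1.0:
        raise ValueError("per-site event probability reaches 1; lower thetas or folds")

    sub_sizes = {g: list(subs.items()) for g, subs in config.populations.items()}
    two_n = {g: 2 * sum(n for _, n in subs) for g, subs in sub_sizes.items()}
    all_subpops = [s for subs in config.populations.values() for s in subs]

    rng_sites = substream(config.seed, "sites")
    rng_daf = substream(config.seed, "daf")
    records: list[VariantRecord] = []
    groups = _site_groups(genome)

    for chrom, per_ctx in groups.items():
        x_scale = config.xi_true if is_x_chromosome(chrom) else 1.0
        for ctx_idx, (positions, flipped) in per_ctx.items():
            events = events_by_ctx[ctx_idx]
            probs = np.array([e[3] * x_scale for e in events])
            draw = rng_sites.multinomial(len(positions), np.append(probs, 1.0 - probs.sum()))
            if draw[:-1].sum() == 0:
                continue
            perm = rng_sites.permutation(len(positions))
            offset = 0
            for (pop, alt, label, _), n_events in zip(events, draw[:-1]):
                if n_events == 0:
                    continue
                chosen = perm[offset : offset + n_events]
                offset += n_events
                site_pos = positions[chosen]
                site_flip = flipped[chosen]
                derived = sample_derived_counts(
                    n_events, two_n[pop], rng_daf, pulse=pulses.get(label)
                )
                polarity_ref = rng_daf.random(n_events) < config.prob_derived_is_ref
                low_conf = rng_daf.random(n_events) < config.prob_low_conf_ancestral
                for j in range(n_events):
                    pos = int(site_pos[j])
                    ref = genome[chrom][pos].upper()
                    actual_alt = _complement(alt) if site_flip[j] else alt
                    ac_pop = int(two_n[pop] - derived[j]) if polarity_ref[j] else int(derived[j])
                    sizes = [2 * n for _, n in sub_sizes[pop]]
                    split = rng_daf.multivariate_hypergeometric(sizes, ac_pop)
                    subpop_ac = {s: 0 for s in all_subpops}
                    for (sub, _), a in zip(sub_sizes[pop], split):
                        subpop_ac[sub] = int(a)
                    subpop_an = {
                        s: 2 * n
                        for subs in config.populations.values()
                        for s, n in subs.items()
                    }
                    ancestral = actual_alt if polarity_ref[j] else ref
                    records.append(
                        VariantRecord(
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=actual_alt,
                            filter_tag="PASS",
                            subpop_ac=subpop_ac,
                            subpop_an=subpop_an,
                            ancestral=ancestral,
                            ancestral_high_conf=not low_conf[j],
                        )
                    )
    records.sort(key=lambda r: (r.chrom, r.pos))
    truth = {
        "theta": {pop: theta.loc[pop].to_dict() for pop in pops},
        "xi_true": config.xi_true,
        "planted_enrichments": [
            {"classes": list(e.classes), "population": e.population, "fold": e.fold}
            for e in config.planted_enrichments
        ],
        "daf_pulses": [vars(p) for p in config.daf_pulses],
        "seed": config.seed,
    }
    return records, truth


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


def write_vcf(records: Sequence[VariantRecord], genome: Mapping[str, str], config: SimulationConfig, path) -> None:
    """Write simulated variants as an uncompressed VCF with per-subpopulation
    AC/AN INFO fields and an AA (ancestral allele) tag."""
    import pysam

    header = pysam.VariantHeader()
    for name, seq in genome.items():
        header.contigs.add(name, length=len(seq))
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele (lowercase = low confidence)">')
    for sub in [s for subs in config.populations.values() for s in subs]:
        header.add_line(
            f'##INFO=<ID=AC_{sub},Number=1,Type=Integer,Description="Alt allele count in {sub}">'
        )
        header.add_line(
            f'##INFO=<ID=AN_{sub},Number=1,Type=Integer,Description="Allele number in {sub}">'
        )
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in records:
            out = vf.new_record(
                contig=rec.chrom,
                start=rec.pos,
                alleles=(rec.ref, rec.alt),
            )
            out.filter.add("PASS")
            aa = rec.ancestral or "."
            if rec.ancestral and not rec.ancestral_high_conf:
                aa = aa.lower()
            out.info["AA"] = aa
            for sub, ac in rec.subpop_ac.items():
                out.info[f"AC_{sub}"] = ac
            for sub, an in rec.subpop_an.items():
                out.info[f"AN_{sub}"] = an
            vf.write(out)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# count-level generators for statistical studies at scale
# --------------------------------------------------------------------------

def simulate_count_table(
    class_probs: pd.DataFrame,
    n_variants: Mapping[str, int] | int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a population x class count table directly at the count level.

    ``class_probs`` holds per-population relative class probabilities
    (rows = populations); each row is normalized and ``n_variants`` private
    variants are distributed multinomially.  This bypasses genome/VCF
    generation for studies whose subject is the counting statistics.
    """
    rows = {}
    for pop in class_probs.index:
        n = n_variants if isinstance(n_variants, int) else n_variants[pop]
        p = class_probs.loc[pop].to_numpy(dtype=float)
        rows[pop] = rng.multinomial(n, p / p.sum())
    table = pd.DataFrame.from_dict(rows, orient="index", columns=class_probs.columns)
    table.index.name = "population"
    return table


def uniform_census(k: int, sites_per_context: int) -> ContextCensus:
    """A census with the same site count for every canonical context.

    Useful for count-level studies where census heterogeneity is not under
    test; 10% of sites are placed on the X partition.
    """
    contexts = canonical_contexts(k)
    x_sites = max(1, sites_per_context // 10)
    frame = pd.DataFrame(
        {"autosomes": sites_per_context - x_sites, "X": x_sites},
        index=pd.Index(contexts),
    )
    return ContextCensus(k=k, counts=frame)
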