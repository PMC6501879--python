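"""Shared fixtures: tiny hand-built VCFs/manifests and a small simulated run."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mutspectra import _io
from mutspectra.simulate import PlantedEnrichment, SimulationConfig, simulate_genome, simulate_private_variants, write_vcf

SUBPOPS = {"LWK": "AFR", "CEU": "EUR", "CHB": "EAS", "GIH": "SAS"}


def make_manifest(subpops: dict[str, str] = SUBPOPS, n_per_sub: int = 4) -> pd.DataFrame:
    rows = [
        {"sample": f"{sub}{i:02d}", "subpopulation": sub, "continent": cont}
        for sub, cont in subpops.items()
        for i in range(n_per_sub)
    ]
    return pd.DataFrame(rows)


VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=q10,Description="Low quality">
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
{info}{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_test_vcf(path: Path, rows, subpops=SUBPOPS, contigs=(("chr1", 100000), ("chrX", 100000))):
    """Write a text VCF with AC_<sub>/AN_<sub> INFO counts.

    Each row is (chrom, pos1, ref, alt, filter, {sub: ac}, an_per_sub[, aa]).
    """
    info = "".join(
        f'##INFO=<ID=AC_{s},Number=1,Type=Integer,Description="x">\n'
        f'##INFO=<ID=AN_{s},Number=1,Type=Integer,Description="x">\n'
        for s in subpops
    )
    contig_lines = "".join(f"##contig=<ID={c},length={l}>\n" for c, l in contigs)
    lines = [VCF_HEADER.format(info=info, contigs=contig_lines)]
    for row in rows:
        chrom, pos, ref, alt, filt, acs, an = row[:7]
        aa = row[7] if len(row) > 7 else ref
        fields = [f"AA={aa}"]
        for sub in subpops:
            fields.append(f"AC_{sub}={acs.get(sub, 0)}")
            fields.append(f"AN_{sub}={an}")
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{';'.join(fields)}\n"
        )
    path.write_text("".join(lines))
    return path


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete simulated study: genome, variants, files on disk."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 250_000, "chr2": 250_000, "chrX": 120_000},
        planted_enrichments=(PlantedEnrichment(("TCC>T",), "EUR", 1.5),),
    )
    genome = simulate_genome(config)
    records, truth = simulate_private_variants(genome, config)
    _io.write_fasta(genome, outdir / "genome.fa")
    write_vcf(records, genome, config, outdir / "variants.vcf")
    config.manifest().to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return {
        "config": config,
        "genome": genome,
        "records": records,
        "truth": truth,
        "dir": outdir,
    }


@pytest.fixture(scope="session")
def small_private_sets(small_sim):
    """Classified continental private sets from the small simulation."""
    from mutspectra.daf import compute_daf
    from mutspectra.filtering import classify_all, extract_private, filter_variants, read_vcf

    manifest = _io.read_manifest(small_sim["dir"] / "manifest.tsv")
    sub_to_cont, _ = _io.manifest_maps(manifest)
    records = read_vcf(small_sim["dir"] / "variants.vcf", manifest)
    filtered, _ = filter_variants(records)
    psets = extract_private(filtered, sorted(set(sub_to_cont.values())), sub_to_cont)
    classify_all(psets, small_sim["genome"])
    for pset in psets.values():
        for rec in pset.variants:
            rec.daf = compute_daf(rec, sub_to_cont)
    return psets


@pytest.fixture(scope="session")
def small_census(small_sim):
    from mutspectra.context import census

    return {k: census(small_sim["genome"], k) for k in (3, 5, 7)}


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
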