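"""Synthetic-data generator: determinism, composition, planted-parameter recovery."""

import numpy as np
import pytest

from mutspectra import _io
from mutspectra.context import census, is_x_chromosome
from mutspectra.simulate import (
    PlantedEnrichment,
    SimulationConfig,
    simulate_count_table,
    simulate_genome,
    simulate_private_variants,
    substream,
    uniform_census,
    write_vcf,
)

SMALL = dict(chrom_lengths={"chr1": 120_000, "chrX": 60_000})


class TestConfigValidation:
    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(seed=1, chrom_lengths={"chr1": 0})

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            SimulationConfig(
                seed=1, planted_enrichments=(PlantedEnrichment(("TCC>T",), "EUR", 0.0),)
            )

    def test_event_probability_reaching_one_rejected(self):
        config = SimulationConfig(
            seed=1,
            **SMALL,
            theta_total={"AFR": 0.2, "EUR": 0.2, "EAS": 0.2, "SAS": 0.2},
            planted_enrichments=(PlantedEnrichment(("TCC>T",), "EUR", 50.0),),
        )
        genome = simulate_genome(config)
        with pytest.raises(ValueError, match="probability"):
            simulate_private_variants(genome, config)


class TestGenome:
    def test_fixed_seed_reproduces_fasta_byte_for_byte(self, tmp_path):
        for run in ("a", "b"):
            config = SimulationConfig(seed=5, **SMALL)
            _io.write_fasta(simulate_genome(config), tmp_path / f"{run}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_base_composition_within_three_se(self):
        comp = (0.3, 0.2, 0.2, 0.3)
        config = SimulationConfig(seed=2, **SMALL, base_composition=comp)
        genome = simulate_genome(config)
        seq = "".join(genome.values())
        n = len(seq)
        for base, p in zip("ACGT", comp):
            se = (p * (1 - p) / n) ** 0.5
            assert abs(seq.count(base) / n - p) < 3 * se

    def test_requested_x_present_with_requested_length(self):
        config = SimulationConfig(seed=3, **SMALL)
        genome = simulate_genome(config)
        assert len(genome["chrX"]) == 60_000
        assert any(is_x_chromosome(c) for c in genome)


class TestVariants:
    def test_records_reproducible_and_private_by_construction(self):
        config = SimulationConfig(seed=9, **SMALL)
        genome = simulate_genome(config)
        recs1, _ = simulate_private_variants(genome, config)
        recs2, _ = simulate_private_variants(genome, config)
        assert [(r.chrom, r.pos, r.alt) for r in recs1] == [
            (r.chrom, r.pos, r.alt) for r in recs2
        ]
        sub_to_cont = config.subpop_to_continent()
        positions = set()
        for rec in recs1:
            assert (rec.chrom, rec.pos) not in positions  # one event per site
            positions.add((rec.chrom, rec.pos))
            observed = {c for c, ac in rec.group_ac(sub_to_cont).items() if ac > 0}
            assert len(observed) == 1
            assert rec.minor_allele_count() >= 2
            assert rec.ref == genome[rec.chrom][rec.pos]

    def test_baseline_proportions_match_within_three_se(self):
        """With no planted folds, each class's realized share of variants is
        binomially consistent with the uniform baseline."""
        config = SimulationConfig(seed=21, chrom_lengths={"chr1": 400_000})
        genome = simulate_genome(config)
        records, _ = simulate_private_variants(genome, config)
        from mutspectra.filtering import classify_all, extract_private
        from mutspectra.tally import tally

        sub_to_cont = config.subpop_to_continent()
        psets = extract_private(records, list(config.populations), sub_to_cont)
        classify_all(psets, genome)
        table = tally(psets, 3)
        cen = census(genome, 3)
        # theta_hat per class vs planted theta, pooled over populations
        for label in ["TCC>T", "AAA>C", "GAT>T"]:
            ctx = label.partition(">")[0]
            n_sites = cen.context_sites(ctx)
            for pop in table.index:
                theta_true = config.effective_theta().loc[pop, label]
                k = table.loc[pop, label]
                se = (theta_true * n_sites) ** 0.5
                assert abs(k - theta_true * n_sites) < 3 * se + 1

    def test_planted_fold_recovered_within_three_se(self):
        fold = 1.5
        config = SimulationConfig(
            seed=17,
            chrom_lengths={"chr1": 500_000, "chr2": 500_000},
            theta_total={"AFR": 2e-3, "EUR": 2e-3, "EAS": 2e-3, "SAS": 2e-3},
            planted_enrichments=(PlantedEnrichment(("TCC>T",), "EUR", fold),),
        )
        genome = simulate_genome(config)
        records, _ = simulate_private_variants(genome, config)
        from mutspectra.filtering import classify_all, extract_private
        from mutspectra.tally import tally

        psets = extract_private(records, list(config.populations), config.subpop_to_continent())
        classify_all(psets, genome)
        table = tally(psets, 3)
        cen = census(genome, 3)
        n_sites = cen.context_sites("TCC")
        theta_eur = table.loc["EUR", "TCC>T"] / n_sites
        theta_afr = table.loc["AFR", "TCC>T"] / n_sites
        ratio = theta_eur / theta_afr
        base = config.class_theta().loc["AFR", "TCC>T"]
        se_ratio = ratio * ((1 / (base * fold * n_sites)) + (1 / (base * n_sites))) ** 0.5
        assert abs(ratio - fold) < 3 * se_ratio

    def test_x_scaling_recovered(self):
        config = SimulationConfig(
            seed=29,
            chrom_lengths={"chr1": 400_000, "chrX": 400_000},
            theta_total={"AFR": 3e-3, "EUR": 3e-3, "EAS": 3e-3, "SAS": 3e-3},
            xi_true=0.5,
        )
        genome = simulate_genome(config)
        records, _ = simulate_private_variants(genome, config)
        from mutspectra.filtering import classify_all, extract_private
        from mutspectra.tally import tally
        from mutspectra.xenrichment import estimate_xi

        psets = extract_private(records, list(config.populations), config.subpop_to_continent())
        classify_all(psets, genome)
        cen = census(genome, 3)
        aut = tally(psets, 3, partition="autosomes")
        onx = tally(psets, 3, partition="X")
        xi_hat = estimate_xi(aut, onx, cen, "AFR")
        n_x = onx.loc["AFR"].sum()
        se = 0.5 / n_x**0.5 * 3  # generous ratio-of-proportions bound
        assert abs(xi_hat - 0.5) < 3 * se

    def test_vcf_round_trip_preserves_counts(self, small_sim, tmp_path):
        from mutspectra.filtering import read_vcf

        manifest = _io.read_manifest(small_sim["dir"] / "manifest.tsv")
        records = read_vcf(small_sim["dir"] / "variants.vcf", manifest)
        originals = {(r.chrom, r.pos): r for r in small_sim["records"]}
        assert len(records) == len(originals)
        for rec in records[:300]:
            orig = originals[(rec.chrom, rec.pos)]
            assert rec.ref == orig.ref and rec.alt == orig.alt
            assert rec.subpop_ac == orig.subpop_ac
            assert rec.ancestral == orig.ancestral
            assert rec.ancestral_high_conf == orig.ancestral_high_conf


class TestCountLevel:
    def test_count_table_margins(self, rng):
        import pandas as pd

        probs = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 1.0], "c": [2.0, 1.0]},
            index=pd.Index(["P1", "P2"], name="population"),
        )
        table = simulate_count_table(probs, {"P1": 1000, "P2": 2000}, rng)
        assert table.loc["P1"].sum() == 1000 and table.loc["P2"].sum() == 2000

    def test_uniform_census_is_uniform(self):
        cen = uniform_census(3, 1000)
        assert cen.counts.sum(axis=1).nunique() == 1
        assert cen.total("X") > 0

    def test_substreams_are_independent_and_stable(self):
        a1 = substream(3, "genome").integers(0, 1000, 5)
        a2 = substream(3, "genome").integers(0, 1000, 5)
        b = substream(3, "daf").integers(0, 1000, 5)
        assert (a1 == a2).all()
        assert not (a1 == b).all()
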