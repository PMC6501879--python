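"""Variant filtering, private-set construction, propagation and classification."""

import numpy as np
import pytest

from mutspectra import _io
from mutspectra.context import fold
from mutspectra.filtering import (
    RefMismatchError,
    VariantRecord,
    classify_variant,
    extract_private,
    filter_variants,
    propagate_to_subpopulations,
    read_vcf,
)

from conftest import SUBPOPS, make_manifest, write_test_vcf


def make_record(chrom="chr1", pos=10, ref="C", alt="T", acs=None, an=8, **kw):
    acs = acs or {"LWK": 2}
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        filter_tag=kw.pop("filter_tag", "PASS"),
        subpop_ac={s: acs.get(s, 0) for s in SUBPOPS},
        subpop_an={s: an for s in SUBPOPS},
        **kw,
    )


class TestFilterVariants:
    def test_toy_vcf_six_records_two_survivors(self, tmp_path):
        rows = [
            ("chr1", 100, "AC", "A", "PASS", {"LWK": 3}, 8),        # indel
            ("chr1", 200, "C", "T", "q10", {"LWK": 3}, 8),          # non-PASS
            ("chr1", 300, "C", "T", "PASS", {"LWK": 3}, 8),         # masked
            ("chr1", 400, "C", "T", "PASS", {"LWK": 1}, 8),         # singleton
            ("chr1", 500, "C", "T", "PASS", {"LWK": 3}, 8),         # passes
            ("chr1", 600, "G", "A", "PASS", {"CEU": 2}, 8),         # passes
        ]
        path = write_test_vcf(tmp_path / "toy.vcf", rows)
        records = read_vcf(path, make_manifest())
        mask = {"chr1": [(250, 350)]}  # 0-based half-open, covers pos1=300
        survivors, stats = filter_variants(records, mask=mask, mac_min=2)
        assert [r.pos for r in survivors] == [499, 599]
        assert stats.as_dict() == {
            "input": 6, "not_snv": 1, "not_pass": 1, "masked": 1,
            "low_mac": 1, "high_missingness": 0, "passed": 2,
        }

    def test_multiallelic_removed(self, tmp_path):
        path = tmp_path / "multi.vcf"
        write_test_vcf(path, [("chr1", 100, "C", "T", "PASS", {"LWK": 3}, 8)])
        text = path.read_text().replace("C\tT\t", "C\tT,G\t")
        path.write_text(text)
        records = read_vcf(path, make_manifest())
        survivors, stats = filter_variants(records)
        assert survivors == [] and stats.not_snv == 1

    def test_filters_commute(self):
        records = [
            make_record(pos=5, acs={"LWK": 1}),
            make_record(pos=10),
            make_record(pos=20, filter_tag="q10"),
            make_record(pos=30, ref="CA", alt="C", is_snv=False),
            make_record(pos=40),
        ]
        mask = {"chr1": [(38, 45)]}
        joint, _ = filter_variants(records, mask=mask, mac_min=2)
        # apply mask-only then MAC-only, and vice versa
        a, _ = filter_variants(records, mask=mask, mac_min=0)
        a, _ = filter_variants(a, mac_min=2)
        b, _ = filter_variants(records, mac_min=2)
        b, _ = filter_variants(b, mask=mask)
        assert [r.pos for r in a] == [r.pos for r in b] == [r.pos for r in joint]

    def test_minor_allele_count_uses_minor_side(self):
        # alt nearly fixed: AC=31 of AN=32 -> minor count 1 -> removed
        rec = make_record(acs={"LWK": 8, "CEU": 8, "CHB": 8, "GIH": 7})
        survivors, stats = filter_variants([rec], mac_min=2)
        assert survivors == [] and stats.low_mac == 1

    def test_missingness_filter(self):
        rec = make_record()
        rec.subpop_an["CHB"] = 5  # 3 of 8 alleles missing in CHB
        kept, _ = filter_variants([rec], missingness=0.5, subpop_sizes={s: 4 for s in SUBPOPS})
        assert kept == [rec]
        dropped, stats = filter_variants([rec], missingness=0.2, subpop_sizes={s: 4 for s in SUBPOPS})
        assert dropped == [] and stats.high_missingness == 1


class TestExtractPrivate:
    S2C = SUBPOPS
    GROUPS = ["AFR", "EUR", "EAS", "SAS"]

    def test_sharing_matrix_fixture(self):
        # 10 variants with a known sharing pattern
        patterns = [
            {"LWK": 2}, {"LWK": 3}, {"LWK": 2},            # AFR-private x3
            {"CEU": 2}, {"CEU": 4},                        # EUR-private x2
            {"CHB": 2},                                    # EAS-private
            {"GIH": 2},                                    # SAS-private
            {"LWK": 2, "CEU": 1},                          # shared -> none
            {"LWK": 1, "CHB": 1},                          # shared -> none
            {"LWK": 1, "CEU": 1, "CHB": 1, "GIH": 1},      # shared -> none
        ]
        records = [make_record(pos=i, acs=p) for i, p in enumerate(patterns)]
        sets = extract_private(records, self.GROUPS, self.S2C)
        assert {g: len(s) for g, s in sets.items()} == {"AFR": 3, "EUR": 2, "EAS": 1, "SAS": 1}
        # pairwise disjoint
        ids = [id(r) for s in sets.values() for r in s.variants]
        assert len(ids) == len(set(ids))
        # exhaustive membership check against the sharing matrix
        for rec in records:
            observed = {self.S2C[s] for s, ac in rec.subpop_ac.items() if ac > 0}
            member_of = [g for g, s in sets.items() if rec in s.variants]
            if len(observed) == 1:
                assert member_of == list(observed)
            else:
                assert member_of == []

    def test_group_without_samples_rejected(self):
        with pytest.raises(ValueError, match="no subpopulations"):
            extract_private([], ["AFR", "OCE"], self.S2C)


class TestPropagation:
    S2C = {"LWK": "AFR", "GWD": "AFR", "CEU": "EUR"}

    def _record(self, acs):
        return VariantRecord(
            chrom="chr1", pos=1, ref="C", alt="T", filter_tag="PASS",
            subpop_ac={s: acs.get(s, 0) for s in self.S2C},
            subpop_an={s: 8 for s in self.S2C},
        )

    def test_variant_seen_in_two_subpops_joins_both_lists(self):
        records = [self._record({"LWK": 2, "GWD": 1}), self._record({"LWK": 2})]
        sets = extract_private(records, ["AFR", "EUR"], self.S2C)
        subs = propagate_to_subpopulations(sets, self.S2C)
        assert len(subs["LWK"]) == 2
        assert len(subs["GWD"]) == 1

    def test_union_of_subpopulation_lists_equals_continent_set(self, rng):
        records = []
        for i in range(50):
            acs = {"LWK": int(rng.integers(0, 4)), "GWD": int(rng.integers(0, 4))}
            if sum(acs.values()) >= 2:
                records.append(self._record(acs))
        sets = extract_private(records, ["AFR", "EUR"], self.S2C)
        subs = propagate_to_subpopulations(sets, self.S2C)
        union = {id(r) for sub in ("LWK", "GWD") for r in subs[sub].variants}
        assert union == {id(r) for r in sets["AFR"].variants}
        for sub in ("LWK", "GWD"):
            for rec in subs[sub].variants:
                assert rec.subpop_ac[sub] > 0

    def test_unassigned_continent_rejected(self):
        from mutspectra.filtering import PrivateVariantSet

        with pytest.raises(ValueError, match="no subpopulations"):
            propagate_to_subpopulations({"OCE": PrivateVariantSet("OCE", [])}, self.S2C)


class TestClassification:
    GENOME = {"chr1": "AATCCGGTAC", "chrX": "ACGNACGTA"}

    def test_three_mer_class_from_flanks(self):
        # site with left flank T, right flank C, ref C, alt T -> TCC>T
        rec = make_record(chrom="chr1", pos=3, ref="C", alt="T")
        classify_variant(rec, self.GENOME)
        assert rec.k3 == "TCC>T"

    def test_complementary_strand_site_gives_same_folded_class(self):
        # GGA>A at chr1:5 (0-based): genome ..CCGG.., flanks G|G with ref G
        genome = {"chr1": "TTGGATT"}
        rec = make_record(chrom="chr1", pos=3, ref="G", alt="A", acs={"LWK": 2})
        classify_variant(rec, genome)
        assert rec.k3 == "TCC>T"

    def test_widths_are_mutually_consistent(self, small_sim):
        from mutspectra.context import MutationClass

        genome = small_sim["genome"]
        for rec in small_sim["records"][:500]:
            classify_variant(rec, genome)
            if rec.k7 is not None:
                m7 = MutationClass.from_label(rec.k7)
                assert m7.trim(5).label == rec.k5
                assert m7.trim(3).label == rec.k3

    def test_matches_string_slicing_oracle(self, small_sim):
        genome = small_sim["genome"]
        for rec in small_sim["records"][:200]:
            classify_variant(rec, genome)
            window = genome[rec.chrom][rec.pos - 1 : rec.pos + 2]
            assert rec.k3 == fold(window, rec.alt).label

    def test_ref_mismatch_raises_with_position(self):
        rec = make_record(chrom="chr1", pos=3, ref="G", alt="T")
        with pytest.raises(RefMismatchError, match="chr1:4"):
            classify_variant(rec, self.GENOME)

    def test_n_in_window_excludes_width_and_wider(self):
        # chrX = ACGNACGTA; site at pos 5 (C): 3-mer ACG ok, 5-mer has N
        rec = make_record(chrom="chrX", pos=5, ref="C", alt="T")
        classify_variant(rec, self.GENOME)
        assert rec.k3 is not None
        assert rec.k5 is None and rec.k7 is None

    def test_edge_site_has_narrow_but_not_wide_class(self):
        rec = make_record(chrom="chr1", pos=1, ref="A", alt="G")
        classify_variant(rec, self.GENOME)
        assert rec.k3 is not None and rec.k7 is None
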