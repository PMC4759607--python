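"""Locus map, coordinate queries, and consequence annotation."""

import itertools

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from mthet.mtgenome import (GENOME_LENGTH, AlleleError, CoordinateError,
                            ReferenceMismatchError, canonical_locus,
                            load_locus_map, substitution_class)
from mthet._refbuild import build_synthetic_reference
from mthet.mtgenome import _data_path


class TestLocusQueries:
    @pytest.mark.parametrize("position, expected", [
        (3243, {"MTTL1"}),            # the MELAS tRNA-Leu(UUR) position
        (8550, {"MTATP8", "MTATP6"}),  # ATP8/ATP6 overlap
        (10763, {"MTND4L", "MTND4"}),  # ND4L/ND4 overlap
        (16100, {"DLOOP"}),
        (400, {"DLOOP"}),             # D-loop wraps the origin
        (5735, set()),                # intergenic gap
        (14300, {"MTND6"}),
    ])
    def test_locus_of(self, locus_map, position, expected):
        assert {l.name for l in locus_map.locus_of(position)} == expected

    @pytest.mark.parametrize("position", [0, -5, 16570, 100000])
    def test_out_of_range_positions_rejected(self, locus_map, position):
        with pytest.raises(CoordinateError):
            locus_map.locus_of(position)

    def test_every_position_maps_deterministically(self, locus_map):
        # full sweep: query succeeds everywhere and agrees with a second pass
        first = [tuple(l.name for l in locus_map.locus_of(p))
                 for p in range(1, GENOME_LENGTH + 1)]
        second = [tuple(l.name for l in locus_map.locus_of(p))
                  for p in range(1, GENOME_LENGTH + 1)]
        assert first == second

    def test_coding_position_count_matches_locus_lengths(self, locus_map):
        coding = locus_map.coding_positions()
        total_len = sum(len(l) for l in locus_map.loci if l.category == "coding")
        overlap = sum(len(v) - 1 for v in coding.values())
        assert len(coding) == total_len - overlap

    def test_dloop_wraps_origin(self, locus_map):
        dl = locus_map["DLOOP"]
        assert dl.wraps and dl.contains(16569) and dl.contains(1)
        assert not dl.contains(577) and dl.contains(576)
        assert len(dl) == (16569 - 16024 + 1) + 576

    def test_aliases(self):
        assert canonical_locus("MTCOX1") == "MTCO1"
        assert canonical_locus("MT-CO1") == "MTCO1"
        assert canonical_locus("MTCYTB") == "MTCYB"
        assert canonical_locus("D-loop") == "DLOOP"


class TestLowComplexityMask:
    @pytest.mark.parametrize("position, expected", [
        (310, True), (302, True), (316, True), (520, True), (16189, True),
        (5000, False), (301, False), (317, False),
    ])
    def test_default_mask(self, locus_map, position, expected):
        assert locus_map.in_low_complexity(position) is expected

    def test_empty_mask(self):
        m = load_locus_map()
        m2 = type(m)(m.loci, m.sequence, low_complexity=())
        assert not any(m2.in_low_complexity(p) for p in (310, 520, 16189))

    def test_bed_mask_round_trip(self, locus_map, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("chrM\t99\t110\n")  # 0-based half-open -> m.100-110
        m = load_locus_map(bed_mask=bed)
        assert m.in_low_complexity(100) and m.in_low_complexity(110)
        assert not m.in_low_complexity(99) and not m.in_low_complexity(111)


class TestSubstitutionClass:
    def test_partition_four_transitions_eight_transversions(self):
        pairs = [(r, a) for r, a in itertools.permutations("ACGT", 2)]
        classes = [substitution_class(r, a) for r, a in pairs]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8

    def test_transition_is_purine_or_pyrimidine_preserving(self):
        assert substitution_class("A", "G") == "transition"
        assert substitution_class("C", "T") == "transition"
        assert substitution_class("A", "C") == "transversion"

    def test_bad_alleles(self):
        with pytest.raises(AlleleError):
            substitution_class("A", "N")
        with pytest.raises(AlleleError):
            substitution_class("A", "A")


class TestAnnotation:
    def test_noncoding_dloop_variant(self, locus_map):
        pos = 16100
        ref = locus_map.ref_base(pos)
        alt = "A" if ref != "A" else "C"
        ann = locus_map.annotate(pos, ref, alt)
        assert ann.consequence == "noncoding"
        assert ann.region_class == "DLOOP"
        assert not ann.coding_effects

    def test_ref_mismatch_rejected(self, locus_map):
        pos = 5000
        wrong = "A" if locus_map.ref_base(pos) != "A" else "C"
        with pytest.raises(ReferenceMismatchError):
            locus_map.annotate(pos, wrong, "G" if wrong != "G" else "T")

    def test_overlap_annotated_independently(self, locus_map):
        pos = 8550
        ref = locus_map.ref_base(pos)
        alt = "A" if ref != "A" else "G"
        ann = locus_map.annotate(pos, ref, alt)
        assert {e.locus for e in ann.coding_effects} == {"MTATP8", "MTATP6"}

    def test_synonymous_vs_whole_protein_oracle(self, locus_map):
        # spot-check vs an independent whole-gene translation (light strand)
        locus = locus_map["MTND6"]
        gene = Seq(locus_map.sequence[locus.start - 1:locus.end])
        gene = gene.reverse_complement()
        ref_protein = str(gene.translate(table=2))
        pos = locus.start + 30
        ref = locus_map.ref_base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            idx = locus.end - pos  # index within the light-strand gene
            mutated = gene[:idx] + str(Seq(alt).reverse_complement()) + gene[idx + 1:]
            alt_protein = str(Seq(mutated).translate(table=2))
            expected = ("nonsynonymous" if alt_protein != ref_protein
                        else "synonymous")
            assert locus_map.annotate(pos, ref, alt).consequence == expected

    def test_incomplete_stop_completed_with_a(self, locus_map):
        # MTND1 ends with a 2-nt incomplete stop (TA + polyA)
        locus = locus_map["MTND1"]
        pos = locus.end  # second base of the incomplete codon
        ref = locus_map.ref_base(pos)
        alt = next(b for b in "ACGT" if b != ref)
        ann = locus_map.annotate(pos, ref, alt)
        effect = next(e for e in ann.coding_effects if e.locus == "MTND1")
        assert len(effect.ref_codon) == 3
        assert effect.ref_codon[2] == "A"  # polyadenylation completion

    @given(st.integers(min_value=1, max_value=GENOME_LENGTH),
           st.sampled_from("ACGT"))
    @settings(max_examples=150, deadline=None)
    def test_annotation_total_over_genome(self, position, alt):
        # property: any valid (position, non-ref alt) annotates without error
        # and reports consistent locus/category tuples
        m = _SESSION_MAP
        ref = m.ref_base(position)
        if alt == ref:
            return
        ann = m.annotate(position, ref, alt)
        assert len(ann.loci) == len(ann.categories)
        assert ann.substitution_class in ("transition", "transversion")
        if "coding" not in ann.categories:
            assert ann.consequence == "noncoding"


_SESSION_MAP = load_locus_map()


class TestReferenceBuild:
    def test_builder_reproduces_bundled_sequence(self, locus_map):
        rebuilt = build_synthetic_reference(_data_path("loci.tsv"))
        assert rebuilt == locus_map.sequence

    def test_coding_frames_have_no_internal_stops_outside_overlaps(
            self, locus_map):
        coding = locus_map.coding_positions()
        for locus in locus_map.loci:
            if locus.category != "coding":
                continue
            seq = locus_map.sequence[locus.start - 1:locus.end]
            if locus.strand == "light":
                seq = str(Seq(seq).reverse_complement())
            n_codons = len(seq) // 3
            for ci in range(n_codons - 1):
                codon_positions = (
                    range(locus.start + ci * 3, locus.start + ci * 3 + 3)
                    if locus.strand == "heavy" else
                    range(locus.end - ci * 3 - 2, locus.end - ci * 3 + 1))
                if any(len(coding[p]) > 1 for p in codon_positions):
                    continue  # overlap codons may hold another gene's signal
                codon = seq[ci * 3:ci * 3 + 3]
                if ci > 0:
                    assert codon not in ("TAA", "TAG", "AGA", "AGG"), (
                        locus.name, ci)
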