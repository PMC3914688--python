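"""Circular-genome data model: coordinates, gene order, junctions, codons."""

import numpy as np
import pytest

from mitojack import pancrustacea
from mitojack.genome import (AnnotationError, CircularGenome,
                             CodonClassificationError, GeneAnnotation,
                             classify_codons, gene_sequence, junction_table,
                             linearize_gene_order, read_feature_table,
                             read_genbank, reverse_complement, strand_counts,
                             write_feature_table, write_genbank)
from mitojack.simulate import simulate_genome


def make_genome(length=100, annotations=(), seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return CircularGenome("toy", seq, True, list(annotations))


class TestGenBankIO:
    def test_plus_strand_cds_coordinates(self, tmp_path):
        g = make_genome(100, [GeneAnnotation("cox1", "J", 0, 9, "PCG")])
        path = tmp_path / "toy.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        ann = back.annotation("cox1")
        assert (ann.start, ann.end, ann.strand) == (0, 9, "J")

    def test_minus_strand_same_coordinates(self, tmp_path):
        g = make_genome(100, [GeneAnnotation("nad5", "N", 0, 9, "PCG")])
        path = tmp_path / "toy.gb"
        write_genbank(g, path)
        ann = read_genbank(path).annotation("nad5")
        assert (ann.start, ann.end, ann.strand) == (0, 9, "N")

    def test_simulated_genome_round_trips(self, tmp_path, sim_genome):
        g, _ = sim_genome
        path = tmp_path / "sim.gb"
        write_genbank(g, path)
        back = read_genbank(path)
        assert len(back) == len(g)
        assert {a.name for a in back.annotations} == {a.name for a in g.annotations}
        for a in g.annotations:
            b = back.annotation(a.name)
            assert (b.start, b.end, b.strand) == (a.start, a.end, a.strand)

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.gb"
        bad.write_text("not a genbank record\n")
        with pytest.raises(AnnotationError):
            read_genbank(bad)


class TestFeatureTable:
    def test_round_trip_exact(self, tmp_path, sim_genome):
        g, _ = sim_genome
        path = tmp_path / "feat.tsv"
        write_feature_table(g, path)
        back = read_feature_table(path, g.seq)
        assert back.annotations == g.annotations

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "feat.tsv"
        path.write_text("wrong\theader\n")
        with pytest.raises(AnnotationError):
            read_feature_table(path, "ACGT")


class TestGeneSequence:
    def test_j_gene_is_slice(self):
        g = CircularGenome("t", "ATGCATGC", True,
                          [GeneAnnotation("x", "J", 0, 4, "tRNA")])
        assert gene_sequence(g, "x") == "ATGC"

    def test_n_gene_is_reverse_complement(self):
        g = CircularGenome("t", "ATGCATGC", True,
                          [GeneAnnotation("x", "N", 0, 4, "tRNA")])
        assert gene_sequence(g, "x") == "GCAT"

    def test_origin_spanning_gene_matches_doubled_sequence(self, rng):
        # brute-force oracle: slicing the doubled sequence
        for _ in range(20):
            L = int(rng.integers(10, 40))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            start = int(rng.integers(L // 2, L))
            end = int(rng.integers(1, L // 2))
            strand = "J" if rng.random() < 0.5 else "N"
            g = CircularGenome("t", seq,
                              True, [GeneAnnotation("x", strand, start, end, "tRNA")])
            expected = (seq + seq)[start : start + (end - start) % L]
            if strand == "N":
                expected = reverse_complement(expected)
            assert gene_sequence(g, "x") == expected

    def test_unknown_gene(self):
        g = make_genome(20, [GeneAnnotation("x", "J", 0, 4, "tRNA")])
        with pytest.raises(KeyError):
            gene_sequence(g, "nope")


class TestGeneOrder:
    def test_template_order_and_strand_counts(self, sim_genome):
        g, _ = sim_genome
        order, found = linearize_gene_order(g)
        assert found
        assert [x for x in order] == list(pancrustacea.GENE_ORDER)
        assert strand_counts(g) == pancrustacea.strand_counts()

    def test_single_gene_genome(self):
        g = make_genome(60, [GeneAnnotation("trnI-gau", "J", 5, 60, "tRNA")])
        order, found = linearize_gene_order(g)
        assert order == [("trnI-gau", "J")] and found

    def test_missing_anchor_flagged(self):
        g = make_genome(100, [GeneAnnotation("cox1", "J", 10, 40, "PCG"),
                              GeneAnnotation("cox2", "J", 50, 90, "PCG")])
        order, found = linearize_gene_order(g)
        assert not found
        assert order[0] == ("cox1", "J")


class TestJunctions:
    def test_abutting_genes(self):
        g = make_genome(100, [GeneAnnotation("a" , "J", 0, 40, "PCG"),
                              GeneAnnotation("b", "J", 40, 80, "PCG")])
        recs = junction_table(g)
        assert recs[0].spacer == 0

    def test_overlap_is_negative(self):
        g = make_genome(100, [GeneAnnotation("nad4", "N", 0, 47, "PCG"),
                              GeneAnnotation("nad4L", "N", 40, 90, "PCG")])
        assert junction_table(g)[0].spacer == -7

    def test_wrap_junction_matches_doubled_sequence_gap(self, rng):
        for _ in range(10):
            L = int(rng.integers(60, 120))
            a_end = int(rng.integers(30, L - 20))
            b_start = int(rng.integers(a_end, L - 10))
            g = make_genome(L, [GeneAnnotation("a", "J", 5, a_end, "PCG"),
                                GeneAnnotation("b", "J", b_start, L - 2, "PCG")])
            wrap = [r for r in junction_table(g) if r.upstream_gene == "b"][0]
            # gap across the origin: 2 nt before the origin plus 5 after
            assert wrap.spacer == 7

    def test_needs_two_genes(self):
        g = make_genome(50, [GeneAnnotation("a", "J", 0, 10, "tRNA")])
        with pytest.raises(AnnotationError):
            junction_table(g)


class TestLengthBookkeeping:
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_gene_lengths_plus_spacers_cover_the_circle(self, seed):
        g, _ = simulate_genome(seed=seed)
        total = sum(a.length(len(g)) for a in g.annotations)
        total += sum(r.spacer for r in junction_table(g))
        assert total == len(g)


class TestCodonClassification:
    @pytest.mark.parametrize("cds,start_cls,stop_cls", [
        ("ATG" + "GCT" * 5 + "TAA", "canonical_ATN", "complete_TAA"),
        ("ATA" + "GCT" * 5 + "TAG", "canonical_ATN", "complete_TAG"),
        ("TTA" + "GCT" * 5 + "T", "noncanonical", "incomplete_T"),
        ("GTG" + "GCT" * 5 + "TA", "noncanonical", "incomplete_TA"),
    ])
    def test_classes(self, cds, start_cls, stop_cls):
        start, stop = classify_codons(cds)
        assert start.classification == start_cls
        assert stop.classification == stop_cls

    @pytest.mark.parametrize("cds", [
        "ATGGCTGCC",        # ends in a sense codon
        "ATGGCTGA",         # 2-nt remainder that is not TA
        "ATGGCTA",          # 1-nt remainder that is not T
        "ANGGCTTAA",        # ambiguity inside the start codon
        "ATG",              # too short
    ])
    def test_rejects(self, cds):
        with pytest.raises(CodonClassificationError):
            classify_codons(cds)

    def test_simulated_pcgs_classify_as_generated(self, sim_genome):
        g, truth = sim_genome
        for gene, info in truth.items():
            if info["class"] != "PCG":
                continue
            assert info["start_call"].codon == info["start"]
            assert info["stop_call"].codon == info["stop"]
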