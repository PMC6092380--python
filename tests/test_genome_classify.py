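import numpy as np
import pytest

from conftest import random_toy_annotation, small_sim_config
from lncweave.genome_classify import (
    classify_lncrna_position,
    filter_putative_lncrnas,
    find_neighbors,
    longest_orf_codons,
    span_gap,
)
from lncweave.io_formats import Gene, GenomeAnnotation, Transcript
from lncweave.synthetic_data import generate_genome


def oracle_classify(annotation, tid, window=50_000):
    """Per-base brute force: set intersections of genomic positions."""
    t = annotation.transcripts[tid]
    g = annotation.genes[t.gene_id]
    span = set(range(t.start, t.end))
    coding = [
        cg for cg in annotation.genes.values()
        if cg.biotype == "protein_coding" and cg.contig == g.contig
    ]
    partners = sorted(
        (cg for cg in coding if span & set(range(cg.start, cg.end))),
        key=lambda cg: cg.gene_id,
    )
    if partners:
        rels = []
        for cg in partners:
            exon_pos = set()
            for tx in annotation.transcripts.values():
                if tx.gene_id == cg.gene_id:
                    for s, e in tx.exons:
                        exon_pos |= set(range(s, e))
            rels.append((0 if span & exon_pos else 1, cg.gene_id))
        rels.sort()
        primary = annotation.genes[rels[0][1]]
        category = "genic_exonic" if rels[0][0] == 0 else "genic_intronic"
        contained = any(
            span <= set(range(cg.start, cg.end)) for cg in partners
        )
        return (
            category,
            "full" if contained else "partial",
            "sense" if g.strand == primary.strand else "antisense",
            [gid for _, gid in rels],
        )
    # intergenic: nearest neighbor by per-base minimum distance
    best = None
    for cg in coding:
        d = min(
            abs(a - b) for a, b in ((t.start, cg.end - 1), (t.end - 1, cg.start))
        )
        d = 0 if (t.start < cg.end and cg.start < t.end) else min(
            abs(t.start - cg.end), abs(cg.start - t.end)
        )
        if d <= window and (best is None or (d, cg.gene_id) < best[:2]):
            best = (d, cg.gene_id, cg.strand)
    if best is None:
        return ("intergenic", "none", "not_applicable", [])
    orient = "sense" if best[2] == g.strand else "antisense"
    return ("intergenic", "none", orient, [])


class TestOrfProxy:
    def test_counts_longest_forward_orf(self):
        seq = "AAATGAAAAAATAAAA"  # ATG then 3 codons then TAA in frame 2
        assert longest_orf_codons(seq) == 3

    def test_orf_without_stop_counts_to_end(self):
        assert longest_orf_codons("ATG" + "GCC" * 10) == 11

    def test_no_atg_means_zero(self):
        assert longest_orf_codons("CCCCCCCCC") == 0


def _one_exon_annotation(entries, contig_len=100_000):
    """entries: (gene_id, biotype, strand, start, end[, exons])."""
    genes, transcripts = {}, {}
    for e in entries:
        gid, biotype, strand, start, end = e[:5]
        exons = e[5] if len(e) > 5 else [(start, end)]
        genes[gid] = Gene(gid, "c1", strand, start, end, biotype)
        transcripts["t_" + gid] = Transcript("t_" + gid, gid, exons)
    return GenomeAnnotation(contig_lengths={"c1": contig_len}, genes=genes, transcripts=transcripts)


class TestPositionalClassification:
    def test_intronic_antisense_fully_contained(self):
        # lncRNA wholly inside the intron of an opposite-strand gene
        ann = _one_exon_annotation([
            ("host", "protein_coding", "+", 1000, 5000, [(1000, 1500), (4500, 5000)]),
            ("lnc", "lncRNA", "-", 2000, 3000),
        ])
        c = classify_lncrna_position("t_lnc", ann)
        assert (c.category, c.overlap, c.orientation) == ("genic_intronic", "full", "antisense")

    def test_exonic_antisense_partial_past_gene_end(self):
        # lncRNA crosses the terminal exon and runs past the gene end
        ann = _one_exon_annotation([
            ("host", "protein_coding", "+", 1000, 5000, [(1000, 1500), (4500, 5000)]),
            ("lnc", "lncRNA", "-", 4800, 6000),
        ])
        c = classify_lncrna_position("t_lnc", ann)
        assert (c.category, c.overlap, c.orientation) == ("genic_exonic", "partial", "antisense")

    def test_lonely_lncrna_is_intergenic(self):
        ann = _one_exon_annotation([("lnc", "lncRNA", "+", 2000, 3000)])
        c = classify_lncrna_position("t_lnc", ann)
        assert (c.category, c.overlap, c.orientation) == ("intergenic", "none", "not_applicable")

    def test_exonic_outranks_intronic_with_multiple_partners(self):
        ann = _one_exon_annotation([
            ("gA", "protein_coding", "+", 1000, 5000, [(1000, 1200), (4800, 5000)]),
            ("gB", "protein_coding", "+", 1500, 2500),
            ("lnc", "lncRNA", "+", 2000, 2400),
        ])
        c = classify_lncrna_position("t_lnc", ann)
        assert c.category == "genic_exonic"  # overlaps gB's exon, only gA's intron
        assert c.partners == ["gB", "gA"]


class TestNeighborSearch:
    def test_window_boundary_inclusive(self):
        ann = _one_exon_annotation([
            ("g", "protein_coding", "+", 0, 1000),
            ("lnc", "lncRNA", "+", 51_000, 52_000),
        ])
        assert len(find_neighbors("t_lnc", ann, window=50_000)) == 1  # gap exactly 50,000

    def test_window_boundary_exclusive_past(self):
        ann = _one_exon_annotation([
            ("g", "protein_coding", "+", 0, 1000),
            ("lnc", "lncRNA", "+", 51_001, 52_000),
        ])
        assert find_neighbors("t_lnc", ann, window=50_000) == []

    def test_distance_convention_1456(self):
        ann = _one_exon_annotation([
            ("stc", "protein_coding", "+", 0, 1000),
            ("lnc", "lncRNA", "-", 2456, 3000),
        ])
        nb = find_neighbors("t_lnc", ann)
        assert nb[0].distance == 1456
        assert nb[0].relative_strand == "antisense"

    def test_overlapping_lncrna_rejected(self):
        ann = _one_exon_annotation([
            ("g", "protein_coding", "+", 0, 1000),
            ("lnc", "lncRNA", "+", 500, 2000),
        ])
        with pytest.raises(ValueError, match="classify_lncrna_position"):
            find_neighbors("t_lnc", ann)

    def test_touching_spans_have_distance_zero(self):
        assert span_gap((0, 100), (100, 200)) == 0


class TestDiscoveryFilters:
    def test_short_transcript_rejected(self):
        cfg = small_sim_config(seed=1)
        ann, _ = generate_genome(cfg)
        # shrink one lncRNA's exons below 200 nt spliced
        tid = next(t for t in ann.transcripts if t.startswith("lnc"))
        t = ann.transcripts[tid]
        s0 = t.exons[0][0]
        t.exons = [(s0, s0 + 90), (s0 + 130, s0 + 190)]
        ann.genes[t.gene_id].end = max(ann.genes[t.gene_id].end, s0 + 190)
        retained, rejected = filter_putative_lncrnas([tid], ann)
        assert rejected[tid].startswith("length")

    def test_sense_adjacent_single_exon_removed_antisense_kept(self):
        import numpy as np

        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        for strand, expect_kept in (("+", False), ("-", True)):
            genes = {
                "g": Gene("g", "c1", "+", 500, 1500, "protein_coding"),
                "lg": Gene("lg", "c1", strand, 1900, 2300, "lncRNA"),
            }
            txs = {
                "m": Transcript("m", "g", [(500, 1500)]),
                "l": Transcript("l", "lg", [(1900, 2300)]),  # single exon, 400 nt away
            }
            ann = GenomeAnnotation(contigs={"c1": seq}, genes=genes, transcripts=txs)
            retained, rejected = filter_putative_lncrnas(["l"], ann)
            if expect_kept:
                assert retained == ["l"] or "ORF" in rejected.get("l", "")
            else:
                assert rejected.get("l") == "sense-adjacent single-exon"

    def test_generated_lncrnas_all_pass(self):
        cfg = small_sim_config(seed=2)
        ann, truth = generate_genome(cfg)
        retained, rejected = filter_putative_lncrnas(sorted(truth.lnc_class), ann)
        assert rejected == {}


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(12))
    def test_structured_genomes_match_truth_and_oracle(self, seed):
        cfg = small_sim_config(seed=seed, n_coding=20, n_lnc=14)
        ann, truth = generate_genome(cfg)
        for tid, rec in truth.lnc_class.items():
            c = classify_lncrna_position(tid, ann)
            assert (c.category, c.overlap, c.orientation) == (
                rec["category"], rec["overlap"], rec["orientation"]
            )
            o_cat, o_ov, o_or, o_partners = oracle_classify(ann, tid)
            assert (c.category, c.overlap, c.orientation) == (o_cat, o_ov, o_or)
            if o_partners:
                assert c.partners == o_partners

    @pytest.mark.parametrize("seed", range(20))
    def test_adversarial_random_genomes_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ann, lnc_ids = random_toy_annotation(rng)
        for tid in lnc_ids:
            c = classify_lncrna_position(tid, ann)
            o_cat, o_ov, o_or, o_partners = oracle_classify(ann, tid)
            assert (c.category, c.overlap, c.orientation) == (o_cat, o_ov, o_or), tid
            if o_partners:
                assert c.partners == o_partners

    def test_categories_partition_the_set(self):
        cfg = small_sim_config(seed=5)
        ann, truth = generate_genome(cfg)
        for tid in truth.lnc_class:
            c = classify_lncrna_position(tid, ann)
            assert c.category in {"genic_exonic", "genic_intronic", "intergenic"}
            assert (c.category == "intergenic") == (c.overlap == "none")
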