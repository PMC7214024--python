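"""Genome/annotation store: loading contracts, interval queries, splicing."""

import random

import pytest
from Bio.Seq import Seq

from fusionprior import load_annotation, load_genome, spliced_sequence
from fusionprior.errors import AnnotationError, GenomeError


class TestLoadGenome:
    def test_case_folding_and_u_to_t(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chrA\nacgu\n")
        g = load_genome(p)
        assert g.contigs == {"chrA": "ACGT"}

    def test_multiple_contigs_lengths_preserved(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGTACGT\n>c2\nGGG\n")
        g = load_genome(p)
        assert len(g.contigs["c1"]) == 8 and len(g.contigs["c2"]) == 3

    def test_duplicate_contig_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chrA\nACGT\n>chrA\nTTTT\n")
        with pytest.raises(GenomeError, match="duplicate contig"):
            load_genome(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(GenomeError, match="no FASTA records"):
            load_genome(p)

    def test_fetch_out_of_range_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nACGT\n")
        g = load_genome(p)
        assert g.fetch("c", 2, 3) == "CG"
        with pytest.raises(GenomeError):
            g.fetch("c", 1, 5)
        with pytest.raises(GenomeError):
            g.fetch("nope", 1, 2)

    def test_fetch_length_matches_interval(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\n" + "ACGT" * 25 + "\n")
        g = load_genome(p)
        rng = random.Random(0)
        for _ in range(50):
            s = rng.randint(1, 100)
            e = rng.randint(s, 100)
            assert len(g.fetch("c", s, e)) == e - s + 1


class TestLoadAnnotation:
    def test_roundtrip_counts_match_generator(self, synth_truth, index):
        assert len(index.genes) == len(synth_truth.genes)
        got_tx = sum(len(g.transcripts) for g in index.genes)
        want_tx = sum(len(g.transcripts) for g in synth_truth.genes)
        assert got_tx == want_tx

    def test_cds_length_multiple_of_three_when_complete(self, index):
        for g in index.genes:
            for tx in g.coding_transcripts():
                if tx.has_annotated_start and tx.has_annotated_stop:
                    total = sum(e - s + 1 for s, e in tx.cds)
                    assert total % 3 == 0

    def test_exons_sorted_and_cds_inside_exons(self, index):
        for g in index.genes:
            for tx in g.transcripts:
                assert tx.exons == sorted(tx.exons)
                for cs, ce in tx.cds:
                    assert any(es <= cs and ce <= ee for es, ee in tx.exons)

    def test_unparseable_line_reports_line_number(self, tmp_path, genome):
        p = tmp_path / "bad.gtf"
        p.write_text("chrS1\tx\tgene\t1\t100\t.\t+\t.\n")  # 8 fields
        with pytest.raises(AnnotationError, match="line 1"):
            load_annotation(p, genome)

    def test_unknown_contig_transcripts_are_counted(self, tmp_path, genome):
        attrs = 'gene_id "gx"; transcript_id "gx.t1";'
        p = tmp_path / "offcontig.gtf"
        p.write_text(
            "\t".join(["chrNOPE", "x", "exon", "1", "30", ".", "+", ".", attrs]) + "\n"
        )
        idx = load_annotation(p, genome)
        assert idx.n_skipped_contigs == 1
        assert len(idx.genes) == 0

    def test_loading_is_deterministic(self, genome_files, genome):
        a = load_annotation(genome_files[1], genome)
        b = load_annotation(genome_files[1], genome)
        assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]
        for ga, gb in zip(a.genes, b.genes):
            assert [(t.transcript_id, t.exons, t.cds) for t in ga.transcripts] == [
                (t.transcript_id, t.exons, t.cds) for t in gb.transcripts
            ]


class TestGenesAt:
    def test_position_inside_one_gene(self, synth_truth, index):
        g = synth_truth.genes[0]
        pos = (g.span[0] + g.span[1]) // 2
        hits = index.genes_at(g.contig, pos)
        assert [h.gene_id for h in hits] == [g.gene_id]

    def test_intergenic_position_is_empty(self, synth_truth, index):
        first = min(g.span[0] for g in synth_truth.genes if g.contig == "chrS1")
        assert index.genes_at("chrS1", max(1, first - 5)) == []

    def test_unknown_contig_is_error(self, index):
        with pytest.raises(AnnotationError, match="unknown contig"):
            index.genes_at("chrZZ", 10)

    def test_overlapping_genes_both_returned(self, tmp_path):
        fasta = tmp_path / "o.fa"
        fasta.write_text(">c\n" + "ACGT" * 50 + "\n")
        genome = load_genome(fasta)
        rows = []
        for gid, s, e in [("g1", 10, 100), ("g2", 50, 150)]:
            rows.append(
                "\t".join(["c", "x", "gene", str(s), str(e), ".", "+", ".", f'gene_id "{gid}";'])
            )
        gtf = tmp_path / "o.gtf"
        gtf.write_text("\n".join(rows) + "\n")
        idx = load_annotation(gtf, genome)
        assert [g.gene_id for g in idx.genes_at("c", 75)] == ["g1", "g2"]
        assert [g.gene_id for g in idx.genes_at("c", 20)] == ["g1"]

    def test_agrees_with_exhaustive_scan(self, synth_truth, index):
        rng = random.Random(17)
        contigs = sorted(synth_truth.contigs)
        for _ in range(1000):
            contig = rng.choice(contigs)
            pos = rng.randint(1, len(synth_truth.contigs[contig]))
            expected = sorted(
                g.gene_id
                for g in synth_truth.genes
                if g.contig == contig and g.span[0] <= pos <= g.span[1]
            )
            assert [g.gene_id for g in index.genes_at(contig, pos)] == expected


class TestSplicedSequence:
    def test_plus_strand_single_exon_is_substring(self, two_gene_locus):
        idx, genome = two_gene_locus["index"], two_gene_locus["genome"]
        tx = idx.gene("GA").transcripts[0]
        assert spliced_sequence(tx, genome, "exons") == genome.fetch("chrT", 11, 23)

    def test_minus_strand_is_reverse_complement(self, tmp_path):
        fasta = tmp_path / "m.fa"
        fasta.write_text(">c\nGGGATGCCCTAAGGG\n")
        genome = load_genome(fasta)
        attrs = 'gene_id "gm"; transcript_id "gm.t1";'
        gtf = tmp_path / "m.gtf"
        gtf.write_text("\t".join(["c", "x", "exon", "4", "12", ".", "-", ".", attrs]) + "\n")
        idx = load_annotation(gtf, genome)
        tx = idx.gene("gm").transcripts[0]
        assert spliced_sequence(tx, genome, "exons") == str(
            Seq(genome.fetch("c", 4, 12)).reverse_complement()
        )

    def test_multi_exon_matches_string_oracle(self, synth_truth, index, genome):
        tx_by_id = {t.transcript_id: t for g in index.genes for t in g.transcripts}
        for g in synth_truth.genes:
            for truth_tx in g.transcripts:
                tx = tx_by_id[truth_tx.transcript_id]
                assert spliced_sequence(tx, genome, "exons") == truth_tx.mrna

    def test_cds_translates_to_truth_protein(self, synth_truth, index, genome):
        tx_by_id = {t.transcript_id: t for g in index.genes for t in g.transcripts}
        for g in synth_truth.genes:
            for truth_tx in g.transcripts:
                tx = tx_by_id[truth_tx.transcript_id]
                cds = spliced_sequence(tx, genome, "cds")
                prot = str(Seq(cds).translate())
                assert prot.endswith("*")
                assert prot[:-1] == truth_tx.protein
                assert tx.has_annotated_start and tx.has_annotated_stop
                assert cds.startswith("ATG") and cds[-3:] in ("TAA", "TAG", "TGA")
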