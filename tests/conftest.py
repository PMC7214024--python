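"""Shared fixtures: generated mini-genomes and a hand-crafted two-gene locus."""

import pathlib

import pytest

from fusionprior import load_annotation, load_genome
from fusionprior.synth import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def synth_truth():
    spec = GenomeSpec(
        n_contigs=2,
        genes_per_contig=6,
        transcripts_per_gene=(1, 3),
        exons_per_transcript=(1, 4),
        seed=3,
    )
    return make_genome(spec)


@pytest.fixture(scope="session")
def genome_files(synth_truth, tmp_path_factory):
    d = tmp_path_factory.mktemp("genome")
    synth_truth.write_fasta(d / "genome.fa")
    synth_truth.write_gtf(d / "annotation.gtf")
    return d / "genome.fa", d / "annotation.gtf"


@pytest.fixture(scope="session")
def genome(genome_files):
    return load_genome(genome_files[0])


@pytest.fixture(scope="session")
def index(genome_files, genome):
    return load_annotation(genome_files[1], genome)


# ---------------------------------------------------------------------------
# hand-crafted locus: two plus-strand single-exon genes with tiny UTRs.
#
#   chrT = G*10 + mRNA_A + G*10 + mRNA_B + G*10
#   mRNA_A = AA ATGGTTTAA AA          (CDS "ATGGTT" + stop TAA -> protein MV)
#   mRNA_B = AAA ATGCTTAAGCCTTGA AA   (protein MLKP)
#
# Genomic coordinates (1-based): gene A spans 11-23 with ATG at 13 and stop
# codon 19-21; gene B spans 34-53 with ATG at 37 and stop codon 49-51.

TWO_GENE_COORDS = {
    "a_cds_start": 13,
    "a_cds_4th_base": 16,   # cutting here retains "ATGG" (mid-codon)
    "a_codon2_end": 18,     # cutting here retains "ATGGTT" (codon boundary)
    "a_stop_end": 21,
    "a_utr3": 22,
    "b_utr5": 35,
    "b_cds_start": 37,
    "b_codon2_start": 40,   # first base of codon 2 ("CTT")
    "b_stop_start": 49,
}


def _two_gene_gtf() -> str:
    def feat(feature, start, end, frame, attrs):
        return "\t".join(["chrT", "test", feature, str(start), str(end), ".", "+", frame, attrs])

    a = 'gene_id "GA"; transcript_id "GA.T1"; gene_name "GENEA";'
    b = 'gene_id "GB"; transcript_id "GB.T1"; gene_name "GENEB";'
    lines = [
        feat("gene", 11, 23, ".", 'gene_id "GA"; gene_name "GENEA"; description "locus A";'),
        feat("transcript", 11, 23, ".", a),
        feat("exon", 11, 23, ".", a),
        feat("CDS", 13, 18, "0", a),
        feat("start_codon", 13, 15, "0", a),
        feat("stop_codon", 19, 21, "0", a),
        feat("gene", 34, 53, ".", 'gene_id "GB"; gene_name "GENEB"; description "locus B";'),
        feat("transcript", 34, 53, ".", b),
        feat("exon", 34, 53, ".", b),
        feat("CDS", 37, 48, "0", b),
        feat("start_codon", 37, 39, "0", b),
        feat("stop_codon", 49, 51, "0", b),
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def two_gene_locus(tmp_path_factory):
    d = tmp_path_factory.mktemp("twogene")
    contig = "G" * 10 + "AA" + "ATGGTTTAA" + "AA" + "G" * 10 + "AAA" + "ATGCTTAAGCCTTGA" + "AA" + "G" * 10
    fasta = d / "two.fa"
    gtf = d / "two.gtf"
    fasta.write_text(">chrT\n" + contig + "\n")
    gtf.write_text(_two_gene_gtf())
    genome = load_genome(fasta)
    index = load_annotation(gtf, genome)
    return {"genome": genome, "index": index, "fasta": fasta, "gtf": gtf, **TWO_GENE_COORDS}
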