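"""Fused-protein construction: junction mechanics, translation, flags."""

import pytest

from fusionprior import Breakpoint, FusionInput, enumerate_candidates
from fusionprior.fusions import (
    _BuildFailure,
    build_candidate,
    build_fused_transcript,
    completeness_flags,
    translate_fused,
)
from fusionprior.synth import make_fusions


def _bp5(locus, key):
    return Breakpoint("chrT", locus[key], "five_prime")


def _bp3(locus, key):
    return Breakpoint("chrT", locus[key], "three_prime")


def _txs(locus):
    idx = locus["index"]
    return idx.gene("GA").transcripts[0], idx.gene("GB").transcripts[0]


class TestTranslateFused:
    def test_natural_stop_not_truncated(self):
        seq, ja, trunc = translate_fused("ATGGCTTAA", 3, 7)
        assert (seq, trunc) == ("MA", False)

    def test_early_stop_truncated(self):
        seq, ja, trunc = translate_fused("ATGTAAGGGCCC", 3, 10)
        assert (seq, trunc) == ("M", True)
        assert ja == 2  # translation stopped before the junction residue

    def test_no_stop_at_all_is_truncated(self):
        seq, _, trunc = translate_fused("ATGGCTGCT", 3, None)
        assert (seq, trunc) == ("MAA", True)

    def test_n_codon_becomes_x(self):
        seq, _, _ = translate_fused("ATGGNTTAA", 3, 7)
        assert seq == "MX"

    def test_too_short_is_failure(self):
        with pytest.raises(_BuildFailure, match="too_short"):
            translate_fused("AT", 0, None)

    def test_junction_aa_midcodon(self):
        # junction_offset 4: residue 2 mixes bases of both genes
        seq, ja, _ = translate_fused("ATGGCTTAA", 4, None)
        assert ja == 2


class TestJunctionMechanics:
    def test_exonic_cut_keeps_breakpoint_base(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        fused, junction, _ = build_fused_transcript(
            txA, _bp5(two_gene_locus, "a_codon2_end"),
            txB, _bp3(two_gene_locus, "b_codon2_start"),
            two_gene_locus["genome"],
        )
        assert fused.startswith("ATGGTT" + "CTTAAGCCTTGA")
        assert junction == 6

    def test_midcodon_cut(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        fused, junction, _ = build_fused_transcript(
            txA, _bp5(two_gene_locus, "a_cds_4th_base"),
            txB, _bp3(two_gene_locus, "b_codon2_start"),
            two_gene_locus["genome"],
        )
        assert fused.startswith("ATGG" + "CTT")
        assert junction == 4

    def test_bp5_before_start_codon_is_skipped(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        with pytest.raises(_BuildFailure, match="no_cds_retained_5p"):
            build_fused_transcript(
                txA, Breakpoint("chrT", 12, "five_prime"),
                txB, _bp3(two_gene_locus, "b_codon2_start"),
                two_gene_locus["genome"],
            )

    def test_bp3_after_stop_codon_is_skipped(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        with pytest.raises(_BuildFailure, match="no_cds_retained_3p"):
            build_fused_transcript(
                txA, _bp5(two_gene_locus, "a_codon2_end"),
                txB, Breakpoint("chrT", 52, "three_prime"),
                two_gene_locus["genome"],
            )

    def test_intronic_bp5_retains_upstream_exons(self, tmp_path):
        # two-exon gene: exon1 1-9 (ATGGTTGGA), intron, exon2 30-35 (CCCTAA)
        from fusionprior import load_annotation, load_genome

        fasta = tmp_path / "i.fa"
        fasta.write_text(">c\n" + "ATGGTTGGA" + "G" * 20 + "CCCTAA" + "A" * 10 + "\n")
        genome = load_genome(fasta)
        attrs = 'gene_id "gi"; transcript_id "gi.t1";'
        rows = [
            ["c", "x", "exon", "1", "9", ".", "+", ".", attrs],
            ["c", "x", "exon", "30", "35", ".", "+", ".", attrs],
            ["c", "x", "CDS", "1", "9", ".", "+", "0", attrs],
            ["c", "x", "CDS", "30", "32", ".", "+", "0", attrs],
            ["c", "x", "stop_codon", "33", "35", ".", "+", "0", attrs],
        ]
        gtf = tmp_path / "i.gtf"
        gtf.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        idx = load_annotation(gtf, genome)
        tx = idx.gene("gi").transcripts[0]
        from fusionprior.fusions import retained_length_5p

        assert retained_length_5p(tx, 15) == 9  # intronic: keep exon 1 only
        assert retained_length_5p(tx, 9) == 9
        assert retained_length_5p(tx, 31) == 11


class TestCompletenessFlags:
    def test_bp5_after_stop_is_five_prime_complete(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        five, three = completeness_flags(
            txA, _bp5(two_gene_locus, "a_utr3"), txB, _bp3(two_gene_locus, "b_codon2_start")
        )
        assert (five, three) == (True, False)

    def test_bp3_before_start_is_three_prime_complete(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        five, three = completeness_flags(
            txA, _bp5(two_gene_locus, "a_codon2_end"), txB, _bp3(two_gene_locus, "b_utr5")
        )
        assert (five, three) == (False, True)

    def test_both_breakpoints_in_cds_neither_complete(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        five, three = completeness_flags(
            txA, _bp5(two_gene_locus, "a_codon2_end"), txB, _bp3(two_gene_locus, "b_codon2_start")
        )
        assert (five, three) == (False, False)


class TestConstructedJunctions:
    def test_phase_preserving_fusion_not_truncated(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        cand = build_candidate(
            txA, _bp5(two_gene_locus, "a_codon2_end"),
            txB, _bp3(two_gene_locus, "b_codon2_start"),
            two_gene_locus["genome"],
        )
        # 2 retained 5' codons (MV) + 3 retained 3' codons (LKP)
        assert cand.sequence == "MVLKP"
        assert cand.truncated is False
        assert cand.in_frame is True
        assert cand.junction_aa == 3

    def test_frameshift_with_early_stop_truncated(self, two_gene_locus):
        txA, txB = _txs(two_gene_locus)
        cand = build_candidate(
            txA, _bp5(two_gene_locus, "a_cds_4th_base"),
            txB, _bp3(two_gene_locus, "b_codon2_start"),
            two_gene_locus["genome"],
        )
        # ATGG + CTTAAG... reads ATG GCT TAA -> early stop
        assert cand.sequence == "MA"
        assert cand.truncated is True
        assert cand.in_frame is False


class TestEnumerateCandidates:
    def test_single_transcript_pair_yields_one_protein(self, two_gene_locus):
        fusion = FusionInput(
            bp5=_bp5(two_gene_locus, "a_codon2_end"),
            bp3=_bp3(two_gene_locus, "b_codon2_start"),
        )
        sets = enumerate_candidates(fusion, two_gene_locus["index"], two_gene_locus["genome"])
        assert len(sets) == 1
        assert sets[0].gene5.gene_id == "GA" and sets[0].gene3.gene_id == "GB"
        assert len(sets[0].proteins) == 1

    def test_intergenic_breakpoint_gives_reasoned_empty_set(self, two_gene_locus):
        fusion = FusionInput(
            bp5=Breakpoint("chrT", 5, "five_prime"),  # in the G padding
            bp3=_bp3(two_gene_locus, "b_codon2_start"),
        )
        sets = enumerate_candidates(fusion, two_gene_locus["index"], two_gene_locus["genome"])
        assert len(sets) == 1
        assert sets[0].proteins == []
        assert sets[0].reason == "no_gene_at_breakpoint"

    def test_candidates_unique_by_sequence_and_sorted(self, synth_truth, index, genome):
        cases = make_fusions(synth_truth, 40, classes=("exonic", "intronic"), seed=5)
        for c in cases:
            for cset in enumerate_candidates(c.fusion, index, genome):
                seqs = [p.sequence for p in cset.proteins]
                assert len(seqs) == len(set(seqs))

    def test_determinism(self, synth_truth, index, genome):
        cases = make_fusions(synth_truth, 10, classes=("exonic",), seed=6)
        for c in cases:
            a = enumerate_candidates(c.fusion, index, genome)
            b = enumerate_candidates(c.fusion, index, genome)
            assert [
                [(p.sequence, p.tx5_id, p.tx3_id) for p in s.proteins] for s in a
            ] == [[(p.sequence, p.tx5_id, p.tx3_id) for p in s.proteins] for s in b]

    def test_matches_string_oracle_on_random_cases(self, synth_truth, index, genome):
        cases = make_fusions(
            synth_truth,
            60,
            classes=("exonic", "intronic", "utr5", "post-stop-5p", "pre-start-3p"),
            seed=8,
        )
        for c in cases:
            got = enumerate_candidates(c.fusion, index, genome)
            exp = c.expected
            assert len(got) == len(exp)
            for s, e in zip(got, exp):
                assert (s.gene5.gene_id if s.gene5 else None) == e["gene5_id"]
                got_c = [
                    (p.sequence, p.tx5_id, p.tx3_id, p.junction_aa, p.truncated,
                     p.five_prime_complete, p.three_prime_complete, p.in_frame)
                    for p in s.proteins
                ]
                exp_c = [
                    (p["sequence"], p["tx5_id"], p["tx3_id"], p["junction_aa"], p["truncated"],
                     p["five_prime_complete"], p["three_prime_complete"], p["in_frame"])
                    for p in e["candidates"]
                ]
                assert got_c == exp_c
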