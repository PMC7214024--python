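"""Candidate fused-protein construction from a pair of genomic breakpoints.

Given a 5' and a 3' breakpoint, every pair of coding transcripts of the
genes overlapping those breakpoints yields one candidate chimeric protein:
the 5' transcript from its annotated start codon through the breakpoint,
concatenated with the 3' transcript from the breakpoint through its end,
translated from the 5' ATG until the first stop codon.

Breakpoint semantics (the dominant fusion-caller convention): the 5'
coordinate is the LAST genomic base retained from the upstream gene and the
3' coordinate is the FIRST genomic base retained from the downstream gene,
both read in transcript orientation.  Intronic breakpoints retain the exons
wholly on the kept side; the breakpoint never creates novel exonic sequence.

Flags per candidate:

* ``truncated`` — the first stop codon reached is not the downstream
  transcript's annotated stop (an early stop occurs in the protein).
* ``five_prime_complete`` — the retained 5' portion includes the upstream
  transcript's stop codon.
* ``three_prime_complete`` — the retained 3' portion includes the
  downstream transcript's start codon.
* ``in_frame`` — the first retained base of the downstream CDS is
  translated in its native codon phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotation import (
    AnnotationIndex,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    spliced_sequence,
)
from .errors import FusionPriorError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# reason codes for attempts that produce no protein
NO_GENE = "no_gene_at_breakpoint"
NO_CDS_5P = "no_cds_retained_5p"
NO_CDS_3P = "no_cds_retained_3p"
TOO_SHORT = "too_short"
EMPTY_PROTEIN = "empty_protein"
NO_CODING_TX = "no_coding_transcripts"


@dataclass(frozen=True)
class Breakpoint:
    contig: str
    position: int  # 1-based genomic coordinate
    role: str  # 'five_prime' or 'three_prime'

    def __post_init__(self):
        if self.position < 1:
            raise FusionPriorError(f"breakpoint position must be >= 1, got {self.position}")
        if self.role not in ("five_prime", "three_prime"):
            raise FusionPriorError(f"invalid breakpoint role {self.role!r}")


@dataclass
class FusionInput:
    bp5: Breakpoint
    bp3: Breakpoint
    source_row: int = 0
    caller_metadata: dict = field(default_factory=dict)


@dataclass
class CandidateProtein:
    sequence: str
    tx5_id: str
    tx3_id: str
    junction_aa: int
    truncated: bool
    five_prime_complete: bool
    three_prime_complete: bool
    in_frame: bool


@dataclass
class FusionCandidateSet:
    fusion: FusionInput
    gene5: GeneModel | None
    gene3: GeneModel | None
    proteins: list[CandidateProtein]
    reason: str = ""
    skipped: dict = field(default_factory=dict)  # reason code -> count


class _BuildFailure(FusionPriorError):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


# ---------------------------------------------------------------------------
# transcript-coordinate arithmetic

def _tx_exons(tx: TranscriptModel) -> list[tuple[int, int]]:
    """Exon intervals in transcript order (5'->3' of the mRNA)."""
    return tx.exons if tx.strand == "+" else list(reversed(tx.exons))


def _tx_offset(tx: TranscriptModel, pos: int) -> int | None:
    """1-based transcript coordinate of genomic ``pos``; None if not exonic."""
    off = 0
    for s, e in _tx_exons(tx):
        if s <= pos <= e:
            return off + (pos - s + 1 if tx.strand == "+" else e - pos + 1)
        off += e - s + 1
    return None


def _tx_length(tx: TranscriptModel) -> int:
    return sum(e - s + 1 for s, e in tx.exons)


def _genomic_to_tx_interval(tx: TranscriptModel, iv: tuple[int, int]) -> tuple[int, int]:
    """Transcript coordinates of a genomic interval fully inside exons."""
    a = _tx_offset(tx, iv[0])
    b = _tx_offset(tx, iv[1])
    assert a is not None and b is not None
    return (min(a, b), max(a, b))


def retained_length_5p(tx: TranscriptModel, pos: int) -> int:
    """Transcript bases retained from the 5' end when cutting at ``pos``.

    Exonic breakpoint: retained through that base inclusive.  Intronic (or
    flanking): retained through the last exon wholly upstream of ``pos`` in
    transcript orientation.
    """
    exact = _tx_offset(tx, pos)
    if exact is not None:
        return exact
    off = 0
    for s, e in _tx_exons(tx):
        upstream = (e < pos) if tx.strand == "+" else (s > pos)
        if upstream:
            off += e - s + 1
        else:
            break
    return off


def retained_start_3p(tx: TranscriptModel, pos: int) -> int:
    """1-based transcript coordinate of the first retained base for the 3' side.

    Returns ``transcript_length + 1`` when nothing is retained.
    """
    exact = _tx_offset(tx, pos)
    if exact is not None:
        return exact
    off = 0
    for s, e in _tx_exons(tx):
        upstream = (e < pos) if tx.strand == "+" else (s > pos)
        if upstream:
            off += e - s + 1
        else:
            return off + 1
    return off + 1  # == length + 1: breakpoint past the transcript end


def _cds_tx_bounds(tx: TranscriptModel) -> tuple[int, int]:
    """(first, last) transcript coordinates of the CDS (stop codon included)."""
    firsts = [_genomic_to_tx_interval(tx, iv) for iv in tx.cds]
    return (min(a for a, _ in firsts), max(b for _, b in firsts))


# ---------------------------------------------------------------------------
# construction

def build_fused_transcript(
    tx5: TranscriptModel,
    bp5: Breakpoint,
    tx3: TranscriptModel,
    bp3: Breakpoint,
    genome: GenomeSequence,
) -> tuple[str, int, int | None]:
    """Fused nucleotide sequence starting at the 5' ATG.

    Returns ``(fused_nt, junction_offset, natural_stop_offset)`` where
    ``junction_offset`` is the length of the retained 5' portion and
    ``natural_stop_offset`` is the 1-based position in ``fused_nt`` of the
    first base of tx3's annotated stop codon, or None when the stop codon is
    not (fully) retained.

    Raises :class:`_BuildFailure` with a reason code when no CDS is retained
    on either side.
    """
    mrna5 = spliced_sequence(tx5, genome, "exons")
    mrna3 = spliced_sequence(tx3, genome, "exons")
    cds5_first, _cds5_last = _cds_tx_bounds(tx5)
    cds3_first, cds3_last = _cds_tx_bounds(tx3)

    L5 = retained_length_5p(tx5, bp5.position)
    if L5 < cds5_first:
        raise _BuildFailure(NO_CDS_5P)
    portion5 = mrna5[cds5_first - 1 : L5]

    S3 = retained_start_3p(tx3, bp3.position)
    if S3 > cds3_last:
        raise _BuildFailure(NO_CDS_3P)
    portion3 = mrna3[S3 - 1 :]

    junction_offset = len(portion5)
    stop_first = cds3_last - 2  # tx coordinate of the stop codon's first base
    natural_stop = None
    if tx3.has_annotated_stop and S3 <= stop_first:
        natural_stop = junction_offset + (stop_first - S3 + 1)
    return portion5 + portion3, junction_offset, natural_stop


def in_frame_flag(tx5: TranscriptModel, bp5: Breakpoint, tx3: TranscriptModel, bp3: Breakpoint) -> bool:
    """True when the retained downstream CDS keeps its native codon phase."""
    cds5_first, _ = _cds_tx_bounds(tx5)
    cds3_first, cds3_last = _cds_tx_bounds(tx3)
    L5 = retained_length_5p(tx5, bp5.position)
    S3 = retained_start_3p(tx3, bp3.position)
    junction_offset = L5 - cds5_first + 1
    first_cds3 = max(S3, cds3_first)
    if first_cds3 > cds3_last:
        return False
    fused_idx0 = junction_offset + (first_cds3 - S3)  # 0-based index in fused nt
    native_idx0 = first_cds3 - cds3_first
    return fused_idx0 % 3 == native_idx0 % 3


def translate_fused(
    fused_nt: str, junction_offset: int, natural_stop_offset: int | None
) -> tuple[str, int, bool]:
    """Translate a fused transcript from position 1 to the first stop codon.

    Returns ``(sequence, junction_aa, truncated)``.  Codons containing N
    become X.  ``truncated`` is True unless the stop reached is exactly the
    downstream transcript's annotated stop codon.
    """
    if len(fused_nt) < 3:
        raise _BuildFailure(TOO_SHORT)
    n_codons = len(fused_nt) // 3
    aa = str(Seq(fused_nt[: 3 * n_codons]).translate())
    stop_idx = aa.find("*")
    if stop_idx >= 0:
        sequence = aa[:stop_idx]
        stop_first_base = 3 * stop_idx + 1
        truncated = natural_stop_offset is None or stop_first_base != natural_stop_offset
    else:
        sequence = aa
        truncated = True  # ran off the end without any stop
    if not sequence:
        raise _BuildFailure(EMPTY_PROTEIN)
    ja = junction_offset // 3 + 1
    junction_aa = ja if ja <= len(sequence) else len(sequence) + 1
    return sequence, junction_aa, truncated


def completeness_flags(
    tx5: TranscriptModel, bp5: Breakpoint, tx3: TranscriptModel, bp3: Breakpoint
) -> tuple[bool, bool]:
    """(five_prime_complete, three_prime_complete) per the report semantics."""
    _, cds5_last = _cds_tx_bounds(tx5)
    cds3_first, _ = _cds_tx_bounds(tx3)
    L5 = retained_length_5p(tx5, bp5.position)
    S3 = retained_start_3p(tx3, bp3.position)
    five_complete = tx5.has_annotated_stop and L5 >= cds5_last
    three_complete = tx3.has_annotated_start and S3 <= cds3_first
    return five_complete, three_complete


def build_candidate(
    tx5: TranscriptModel,
    bp5: Breakpoint,
    tx3: TranscriptModel,
    bp3: Breakpoint,
    genome: GenomeSequence,
) -> CandidateProtein:
    """One candidate protein for one transcript pair; raises _BuildFailure on skips."""
    fused, junction, natural_stop = build_fused_transcript(tx5, bp5, tx3, bp3, genome)
    sequence, junction_aa, truncated = translate_fused(fused, junction, natural_stop)
    five_c, three_c = completeness_flags(tx5, bp5, tx3, bp3)
    return CandidateProtein(
        sequence=sequence,
        tx5_id=tx5.transcript_id,
        tx3_id=tx3.transcript_id,
        junction_aa=junction_aa,
        truncated=truncated,
        five_prime_complete=five_c,
        three_prime_complete=three_c,
        in_frame=in_frame_flag(tx5, bp5, tx3, bp3),
    )


def enumerate_candidates(
    fusion: FusionInput, index: AnnotationIndex, genome: GenomeSequence
) -> list[FusionCandidateSet]:
    """All candidate sets for a fusion, one per (gene5, gene3) pair.

    Transcript pairs that cannot yield a protein are skipped and counted in
    ``FusionCandidateSet.skipped``.  If no gene overlaps a breakpoint a
    single empty set with reason ``no_gene_at_breakpoint`` is returned.
    """
    genes5 = index.genes_at(fusion.bp5.contig, fusion.bp5.position)
    genes3 = index.genes_at(fusion.bp3.contig, fusion.bp3.position)
    if not genes5 or not genes3:
        return [FusionCandidateSet(fusion, None, None, [], reason=NO_GENE)]

    sets: list[FusionCandidateSet] = []
    for g5 in genes5:
        for g3 in genes3:
            tx5s = sorted(g5.coding_transcripts(), key=lambda t: t.transcript_id)
            tx3s = sorted(g3.coding_transcripts(), key=lambda t: t.transcript_id)
            skipped: dict[str, int] = {}
            proteins: list[CandidateProtein] = []
            seen: set[str] = set()
            if not tx5s or not tx3s:
                sets.append(FusionCandidateSet(fusion, g5, g3, [], reason=NO_CODING_TX))
                continue
            first_reason = ""
            for tx5 in tx5s:
                for tx3 in tx3s:
                    try:
                        cand = build_candidate(tx5, fusion.bp5, tx3, fusion.bp3, genome)
                    except _BuildFailure as exc:
                        skipped[exc.reason] = skipped.get(exc.reason, 0) + 1
                        first_reason = first_reason or exc.reason
                        continue
                    if cand.sequence not in seen:
                        seen.add(cand.sequence)
                        proteins.append(cand)
            reason = "" if proteins else first_reason
            sets.append(
                FusionCandidateSet(fusion, g5, g3, proteins, reason=reason, skipped=skipped)
            )
    return sets
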