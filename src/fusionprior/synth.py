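"""Deterministic synthetic fixtures: mini-genomes, fusions, labeled datasets.

Everything here is generated from a seed and written as plain text (FASTA,
GTF, TSV, JSON), so the rest of the package is testable without downloads.
Three generators are provided:

* :func:`make_genome` — a multi-gene mini-genome with known transcripts and
  proteins (truth tables included).
* :func:`make_fusions` — breakpoint cases of requested classes (exonic,
  intronic, UTR, post-stop, pre-start, intergenic) whose expected fused
  proteins and flags are computed by a naive string-splice oracle.
* :func:`make_labeled_dataset` — amino-acid sequences with a planted
  discriminative motif in the positive class, optionally backed by a
  generated genome plus an N x 5 breakpoint file whose fused proteins
  carry the motif according to the label.

The oracle in this module deliberately shares no code with the fusion
builder: it works on the truth tables' mRNA strings with plain slicing and
an explicit codon dictionary, so agreement between the two is a real check.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict

from .fusions import Breakpoint, FusionInput

# explicit standard codon table (oracle-side; the builder uses Biopython)
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA_ORDER[i * 16 + j * 4 + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOPS = sorted(c for c, aa in CODON_TABLE.items() if aa == "*")
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    if aa != "*":
        AA_TO_CODONS.setdefault(aa, []).append(codon)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

FUSION_CLASSES = (
    "exonic",
    "intronic",
    "utr5",
    "post-stop-5p",
    "pre-start-3p",
    "intergenic",
)


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome truth

@dataclass
class GenomeSpec:
    n_contigs: int = 1
    genes_per_contig: int = 4
    transcripts_per_gene: tuple[int, int] = (1, 2)
    exons_per_transcript: tuple[int, int] = (1, 3)
    cds_codons: tuple[int, int] = (25, 60)  # codons including start and stop
    utr5_len: tuple[int, int] = (3, 30)
    utr3_len: tuple[int, int] = (3, 30)
    intron_len: tuple[int, int] = (20, 80)
    intergenic_gap: tuple[int, int] = (60, 150)
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def validate(self):
        for name in (
            "transcripts_per_gene",
            "exons_per_transcript",
            "cds_codons",
            "utr5_len",
            "utr3_len",
            "intron_len",
            "intergenic_gap",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise SynthError(f"invalid range for {name}: ({lo}, {hi})")
        if self.cds_codons[0] < 4:
            raise SynthError("cds_codons lower bound must be >= 4 (start + 2 + stop)")
        if self.n_contigs < 1 or self.genes_per_contig < 1:
            raise SynthError("need at least one contig and one gene per contig")
        if self.intergenic_gap[0] < 1:
            raise SynthError("intergenic gap too small for distinct genes")


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    mrna: str  # transcript orientation
    utr5_len: int
    cds_len: int  # nucleotides, stop codon included
    protein: str  # stop excluded
    exon_map: list[tuple[int, int, int, int]]  # (m_start, m_end, g_start, g_end), tx order

    @property
    def cds_first(self) -> int:  # mRNA coordinate of the A of ATG
        return self.utr5_len + 1

    @property
    def cds_last(self) -> int:  # mRNA coordinate of the stop codon's last base
        return self.utr5_len + self.cds_len

    def mrna_pos(self, g: int) -> int | None:
        """mRNA coordinate of genomic position ``g``; None when intronic/outside."""
        for ms, me, gs, ge in self.exon_map:
            if gs <= g <= ge:
                return ms + (g - gs) if self.strand == "+" else ms + (ge - g)
        return None

    def genomic_intervals(self, m1: int, m2: int) -> list[tuple[int, int]]:
        """Genomic intervals covering the mRNA range [m1, m2], genomic order."""
        out = []
        for ms, me, gs, ge in self.exon_map:
            lo, hi = max(m1, ms), min(m2, me)
            if lo > hi:
                continue
            if self.strand == "+":
                out.append((gs + (lo - ms), gs + (hi - ms)))
            else:
                out.append((ge - (hi - ms), ge - (lo - ms)))
        return sorted(out)

    def genomic_pos(self, m: int) -> int:
        iv = self.genomic_intervals(m, m)
        if not iv:
            raise SynthError(f"mRNA coordinate {m} outside transcript {self.transcript_id}")
        return iv[0][0]


@dataclass
class GeneTruth:
    gene_id: str
    name: str
    contig: str
    strand: str
    span: tuple[int, int]
    transcripts: list[TranscriptTruth] = field(default_factory=list)


@dataclass
class GenomeTruth:
    contigs: dict[str, str]
    genes: list[GeneTruth]
    spec: GenomeSpec

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.contigs:
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gtf(self, path) -> None:
        lines: list[tuple[str, int, str]] = []  # (contig, start, line) for ordering
        for gene in self.genes:
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.name}"; '
                f'description "synthetic gene {gene.gene_id}";'
            )
            lines.append(
                (
                    gene.contig,
                    gene.span[0],
                    "\t".join(
                        [
                            gene.contig,
                            "synth",
                            "gene",
                            str(gene.span[0]),
                            str(gene.span[1]),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    ),
                )
            )
            for tx in gene.transcripts:
                t_attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{gene.name}"; transcript_biotype "protein_coding";'
                )
                exons = sorted((gs, ge) for _, _, gs, ge in tx.exon_map)
                span = (exons[0][0], exons[-1][1])
                rows = [("transcript", span[0], span[1], ".")]
                for gs, ge in exons:
                    rows.append(("exon", gs, ge, "."))
                # Ensembl convention: CDS excludes the stop codon
                cum = 0
                frames = []
                for m1, m2 in self._cds_tx_chunks(tx):
                    frames.append((3 - cum % 3) % 3)
                    cum += m2 - m1 + 1
                tx_order = tx.genomic_intervals(tx.cds_first, tx.cds_last - 3)
                if tx.strand == "-":
                    frames = list(reversed(frames))
                for (gs, ge), fr in zip(tx_order, frames):
                    rows.append(("CDS", gs, ge, str(fr)))
                for gs, ge in tx.genomic_intervals(tx.cds_first, tx.cds_first + 2):
                    rows.append(("start_codon", gs, ge, "0"))
                for gs, ge in tx.genomic_intervals(tx.cds_last - 2, tx.cds_last):
                    rows.append(("stop_codon", gs, ge, "0"))
                for feat, gs, ge, fr in rows:
                    lines.append(
                        (
                            gene.contig,
                            gs,
                            "\t".join(
                                [
                                    gene.contig,
                                    "synth",
                                    feat,
                                    str(gs),
                                    str(ge),
                                    ".",
                                    gene.strand,
                                    fr,
                                    t_attrs,
                                ]
                            ),
                        )
                    )
        with open(path, "w") as fh:
            for _, _, line in lines:
                fh.write(line + "\n")

    @staticmethod
    def _cds_tx_chunks(tx: TranscriptTruth) -> list[tuple[int, int]]:
        """CDS (stop excluded) split at exon boundaries, in transcript order."""
        out = []
        for ms, me, _gs, _ge in tx.exon_map:
            lo, hi = max(tx.cds_first, ms), min(tx.cds_last - 3, me)
            if lo <= hi:
                out.append((lo, hi))
        return out

    def write_truth_json(self, path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "name": g.name,
                    "contig": g.contig,
                    "strand": g.strand,
                    "span": list(g.span),
                    "transcripts": [
                        {
                            "transcript_id": t.transcript_id,
                            "protein": t.protein,
                            "utr5_len": t.utr5_len,
                            "cds_len": t.cds_len,
                            "exon_map": [list(e) for e in t.exon_map],
                        }
                        for t in g.transcripts
                    ],
                }
                for g in self.genes
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    # convenience lookups -------------------------------------------------
    def genes_containing(self, contig: str, pos: int) -> list[GeneTruth]:
        return [
            g
            for g in self.genes
            if g.contig == contig and g.span[0] <= pos <= g.span[1]
        ]


# ---------------------------------------------------------------------------
# genome construction

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_cds(rng: random.Random, n_codons: int) -> str:
    """ATG + (n-2) non-stop codons + one stop codon."""
    non_stop = sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*")
    interior = "".join(rng.choice(non_stop) for _ in range(n_codons - 2))
    return "ATG" + interior + rng.choice(STOPS)


def _translate_oracle(nt: str) -> tuple[str, int | None]:
    """(residues before first stop, 1-based nt position of the stop's first base)."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa = CODON_TABLE.get(codon, "X")
        if aa == "*":
            return "".join(aas), i + 1
        aas.append(aa)
    return "".join(aas), None


def _split_exons(rng: random.Random, length: int, n_exons: int) -> list[tuple[int, int]]:
    """Partition [1, length] into n contiguous non-empty mRNA pieces."""
    n_exons = min(n_exons, length)
    cuts = sorted(rng.sample(range(1, length), n_exons - 1)) if n_exons > 1 else []
    bounds = [0] + cuts + [length]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(n_exons)]


def _make_transcript_layout(
    rng: random.Random, spec: GenomeSpec
) -> tuple[str, int, int, list[tuple[int, int]], list[str]]:
    """Primary transcript: mRNA, UTR lengths, exon mRNA pieces, introns."""
    utr5 = rng.randint(*spec.utr5_len)
    utr3 = rng.randint(*spec.utr3_len)
    n_codons = rng.randint(*spec.cds_codons)
    cds = _random_cds(rng, n_codons)
    mrna = _random_nt(rng, utr5) + cds + _random_nt(rng, utr3)
    n_ex = rng.randint(*spec.exons_per_transcript)
    pieces = _split_exons(rng, len(mrna), n_ex)
    introns = [_random_nt(rng, rng.randint(*spec.intron_len)) for _ in range(len(pieces) - 1)]
    return mrna, utr5, len(cds), pieces, introns


def _skip_isoform(
    rng: random.Random, mrna: str, utr5: int, cds_len: int, pieces: list[tuple[int, int]]
) -> tuple[str, int, list[tuple[int, int]], int] | None:
    """Try to derive an exon-skipping isoform that stays a clean ORF.

    Returns (new_mrna, new_cds_len, kept piece indices as new pieces, skipped
    index) or None when no internal exon can be skipped without breaking the
    frame or introducing a premature stop.
    """
    candidates = []
    for j in range(1, len(pieces) - 1):
        a, b = pieces[j]
        ln = b - a + 1
        inside_cds = a > utr5 + 3 and b < utr5 + cds_len - 2
        if ln % 3 == 0 and inside_cds:
            new_mrna = mrna[: a - 1] + mrna[b:]
            new_cds = new_mrna[utr5 : utr5 + cds_len - ln]
            prot, stop_pos = _translate_oracle(new_cds)
            if stop_pos == len(new_cds) - 2:  # stop only at the final codon
                candidates.append((j, new_mrna, cds_len - ln))
    if not candidates:
        return None
    j, new_mrna, new_cds_len = candidates[rng.randrange(len(candidates))]
    return new_mrna, new_cds_len, pieces, j


def make_genome(spec: GenomeSpec) -> GenomeTruth:
    """Generate a mini-genome with annotation truth, deterministic per seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    contigs: dict[str, str] = {}
    genes: list[GeneTruth] = []
    gene_no = 0
    for ci in range(spec.n_contigs):
        contig = f"chrS{ci + 1}"
        parts: list[str] = []
        pos = 0  # 0-based length so far
        for _gi in range(spec.genes_per_contig):
            gene_no += 1
            gap = rng.randint(*spec.intergenic_gap)
            parts.append(_random_nt(rng, gap))
            pos += gap
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            gene_id = f"SYNG{gene_no:04d}"
            mrna, utr5, cds_len, pieces, introns = _make_transcript_layout(rng, spec)
            # pre-mRNA in transcript orientation
            pre_chunks = []
            for k, (a, b) in enumerate(pieces):
                pre_chunks.append(mrna[a - 1 : b])
                if k < len(introns):
                    pre_chunks.append(introns[k])
            pre = "".join(pre_chunks)
            gene_seq = pre if strand == "+" else _revcomp(pre)
            gene_start = pos + 1  # 1-based
            # pre-mRNA coordinate of each exon piece
            pre_pos = 0
            pre_spans = []
            for k, (a, b) in enumerate(pieces):
                ln = b - a + 1
                pre_spans.append((pre_pos + 1, pre_pos + ln))
                pre_pos += ln
                if k < len(introns):
                    pre_pos += len(introns[k])
            L = len(pre)

            def _exon_map(pieces_m, cds_shift_after=None):
                out = []
                for (ms, me), (ps, pe) in zip(pieces_m, pre_spans):
                    if strand == "+":
                        gs, ge = gene_start + ps - 1, gene_start + pe - 1
                    else:
                        gs, ge = gene_start + (L - pe), gene_start + (L - ps)
                    out.append((ms, me, gs, ge))
                return out

            n_tx = rng.randint(*spec.transcripts_per_gene)
            transcripts: list[TranscriptTruth] = []
            primary_map = _exon_map(pieces)
            prot, _ = _translate_oracle(mrna[utr5 : utr5 + cds_len])
            transcripts.append(
                TranscriptTruth(
                    transcript_id=f"{gene_id}.T1",
                    gene_id=gene_id,
                    contig=contig,
                    strand=strand,
                    mrna=mrna,
                    utr5_len=utr5,
                    cds_len=cds_len,
                    protein=prot,
                    exon_map=primary_map,
                )
            )
            for ti in range(2, n_tx + 1):
                iso = _skip_isoform(rng, mrna, utr5, cds_len, pieces)
                if iso is not None:
                    new_mrna, new_cds_len, _pieces, j = iso
                    skip_len = pieces[j][1] - pieces[j][0] + 1
                    new_map = []
                    shift = 0
                    for k, (ms, me, gs, ge) in enumerate(primary_map):
                        if k == j:
                            shift = skip_len
                            continue
                        new_map.append((ms - shift, me - shift, gs, ge))
                    new_prot, _ = _translate_oracle(new_mrna[utr5 : utr5 + new_cds_len])
                    transcripts.append(
                        TranscriptTruth(
                            transcript_id=f"{gene_id}.T{ti}",
                            gene_id=gene_id,
                            contig=contig,
                            strand=strand,
                            mrna=new_mrna,
                            utr5_len=utr5,
                            cds_len=new_cds_len,
                            protein=new_prot,
                            exon_map=new_map,
                        )
                    )
                else:
                    # same structure under a second id (exercises deduplication)
                    transcripts.append(
                        TranscriptTruth(
                            transcript_id=f"{gene_id}.T{ti}",
                            gene_id=gene_id,
                            contig=contig,
                            strand=strand,
                            mrna=mrna,
                            utr5_len=utr5,
                            cds_len=cds_len,
                            protein=prot,
                            exon_map=primary_map,
                        )
                    )
            parts.append(gene_seq)
            pos += len(gene_seq)
            genes.append(
                GeneTruth(
                    gene_id=gene_id,
                    name=f"SYN{gene_no}",
                    contig=contig,
                    strand=strand,
                    span=(gene_start, pos),
                    transcripts=transcripts,
                )
            )
        parts.append(_random_nt(rng, rng.randint(*spec.intergenic_gap)))
        contigs[contig] = "".join(parts)
    return GenomeTruth(contigs=contigs, genes=genes, spec=spec)


# ---------------------------------------------------------------------------
# fusion oracle

def _oracle_L5(tx: TranscriptTruth, pos: int) -> int:
    m = tx.mrna_pos(pos)
    if m is not None:
        return m
    off = 0
    for ms, me, gs, ge in tx.exon_map:
        upstream = (ge < pos) if tx.strand == "+" else (gs > pos)
        if upstream:
            off = me
        else:
            break
    return off


def _oracle_S3(tx: TranscriptTruth, pos: int) -> int:
    m = tx.mrna_pos(pos)
    if m is not None:
        return m
    for ms, me, gs, ge in tx.exon_map:
        downstream = (gs > pos) if tx.strand == "+" else (ge < pos)
        if downstream:
            return ms
    return len(tx.mrna) + 1


def oracle_pair(
    tx5: TranscriptTruth, bp5_pos: int, tx3: TranscriptTruth, bp3_pos: int
) -> dict | None:
    """Expected candidate for one transcript pair, or None when skipped."""
    L5 = _oracle_L5(tx5, bp5_pos)
    if L5 < tx5.cds_first:
        return None
    S3 = _oracle_S3(tx3, bp3_pos)
    if S3 > tx3.cds_last:
        return None
    portion5 = tx5.mrna[tx5.utr5_len : L5]
    portion3 = tx3.mrna[S3 - 1 :]
    fused = portion5 + portion3
    if len(fused) < 3:
        return None
    seq, stop_pos = _translate_oracle(fused)
    if not seq:
        return None
    j = len(portion5)
    stop_first = tx3.cds_last - 2
    natural = j + (stop_first - S3 + 1) if S3 <= stop_first else None
    truncated = stop_pos is None or natural is None or stop_pos != natural
    ja = j // 3 + 1
    junction_aa = ja if ja <= len(seq) else len(seq) + 1
    five_complete = L5 >= tx5.cds_last
    three_complete = S3 <= tx3.cds_first
    first_cds3 = max(S3, tx3.cds_first)
    if first_cds3 > tx3.cds_last:
        in_frame = False
    else:
        fused_idx0 = j + (first_cds3 - S3)
        native_idx0 = first_cds3 - tx3.cds_first
        in_frame = fused_idx0 % 3 == native_idx0 % 3
    return {
        "sequence": seq,
        "tx5_id": tx5.transcript_id,
        "tx3_id": tx3.transcript_id,
        "junction_aa": junction_aa,
        "truncated": truncated,
        "five_prime_complete": five_complete,
        "three_prime_complete": three_complete,
        "in_frame": in_frame,
    }


def oracle_candidates(truth: GenomeTruth, bp5: Breakpoint, bp3: Breakpoint) -> list[dict]:
    """Expected candidate sets for a fusion, one dict per (gene5, gene3) pair."""
    genes5 = sorted(truth.genes_containing(bp5.contig, bp5.position), key=lambda g: g.gene_id)
    genes3 = sorted(truth.genes_containing(bp3.contig, bp3.position), key=lambda g: g.gene_id)
    if not genes5 or not genes3:
        return [{"gene5_id": None, "gene3_id": None, "candidates": [], "reason": "no_gene_at_breakpoint"}]
    sets = []
    for g5 in genes5:
        for g3 in genes3:
            seen: set[str] = set()
            cands = []
            for tx5 in sorted(g5.transcripts, key=lambda t: t.transcript_id):
                for tx3 in sorted(g3.transcripts, key=lambda t: t.transcript_id):
                    c = oracle_pair(tx5, bp5.position, tx3, bp3.position)
                    if c is not None and c["sequence"] not in seen:
                        seen.add(c["sequence"])
                        cands.append(c)
            sets.append(
                {"gene5_id": g5.gene_id, "gene3_id": g3.gene_id, "candidates": cands, "reason": ""}
            )
    return sets


# ---------------------------------------------------------------------------
# fusion case sampling

@dataclass
class FusionTruth:
    fusion: FusionInput
    fusion_class: str
    expected: list[dict]  # oracle_candidates output
    label: int | None = None


def _sample_position(rng: random.Random, truth: GenomeTruth, gene: GeneTruth, side: str, cls: str) -> int:
    """Genomic breakpoint position in ``gene`` for a class, or raise SynthError."""
    tx = gene.transcripts[0]  # primary transcript defines the class geometry
    if cls == "exonic":
        m = rng.randint(tx.cds_first, tx.cds_last)
        return tx.genomic_pos(m)
    if cls == "intronic":
        multi = [t for t in gene.transcripts if len(t.exon_map) >= 2]
        if not multi:
            raise SynthError("class 'intronic' impossible: no multi-exon transcript in gene")
        t = multi[0]
        exons = sorted((gs, ge) for _, _, gs, ge in t.exon_map)
        k = rng.randrange(len(exons) - 1)
        lo, hi = exons[k][1] + 1, exons[k + 1][0] - 1
        if lo > hi:
            raise SynthError("class 'intronic' impossible: zero-length intron")
        return rng.randint(lo, hi)
    if cls == "utr5":
        if tx.utr5_len < 1:
            raise SynthError("class 'utr5' impossible: transcript has no 5' UTR")
        return tx.genomic_pos(rng.randint(1, tx.utr5_len))
    if cls == "post-stop-5p":
        if tx.cds_last >= len(tx.mrna):
            raise SynthError("class 'post-stop-5p' impossible: no 3' UTR")
        return tx.genomic_pos(rng.randint(tx.cds_last + 1, len(tx.mrna)))
    if cls == "pre-start-3p":
        if tx.utr5_len < 1:
            raise SynthError("class 'pre-start-3p' impossible: transcript has no 5' UTR")
        return tx.genomic_pos(rng.randint(1, tx.utr5_len))
    raise SynthError(f"unknown fusion class {cls!r}")


def _intergenic_position(rng: random.Random, truth: GenomeTruth) -> tuple[str, int]:
    contig = rng.choice(sorted(truth.contigs))
    spans = sorted(g.span for g in truth.genes if g.contig == contig)
    gaps = []
    prev = 0
    for s, e in spans:
        if s - prev > 2:
            gaps.append((prev + 1, s - 1))
        prev = max(prev, e)
    if len(truth.contigs[contig]) - prev > 1:
        gaps.append((prev + 1, len(truth.contigs[contig])))
    if not gaps:
        raise SynthError("class 'intergenic' impossible: no intergenic space")
    lo, hi = gaps[rng.randrange(len(gaps))]
    return contig, rng.randint(lo, hi)


def make_fusions(
    truth: GenomeTruth,
    n: int,
    classes: tuple[str, ...] = ("exonic", "intronic"),
    seed: int = 0,
) -> list[FusionTruth]:
    """Sample ``n`` fusion cases cycling over the requested classes.

    Breakpoint classes describe the 5' side except ``pre-start-3p`` which
    places the 3' breakpoint upstream of the downstream start codon; the
    unconstrained side is exonic.  Expected candidates come from the naive
    string oracle.
    """
    for cls in classes:
        if cls not in FUSION_CLASSES:
            raise SynthError(f"unknown fusion class {cls!r}")
    rng = random.Random(seed)
    genes = [g for g in truth.genes if g.transcripts]
    if len(genes) < 2:
        raise SynthError("need at least two genes to build fusions")

    def _eligible(cls: str) -> list[GeneTruth]:
        if cls == "intronic":
            out = [g for g in genes if any(len(t.exon_map) >= 2 for t in g.transcripts)]
        elif cls in ("utr5", "pre-start-3p"):
            out = [g for g in genes if g.transcripts[0].utr5_len >= 1]
        elif cls == "post-stop-5p":
            out = [g for g in genes if g.transcripts[0].cds_last < len(g.transcripts[0].mrna)]
        else:
            out = genes
        if not out:
            raise SynthError(f"class {cls!r} impossible on this genome")
        return out

    cases: list[FusionTruth] = []
    for i in range(n):
        cls = classes[i % len(classes)]
        side = "3p" if cls == "pre-start-3p" else "5p"
        pool = _eligible(cls)
        if side == "5p":
            g5 = rng.choice(pool)
            g3 = rng.choice([g for g in genes if g is not g5])
        else:
            g3 = rng.choice(pool)
            g5 = rng.choice([g for g in genes if g is not g3])
        if cls == "intergenic":
            contig, pos5 = _intergenic_position(rng, truth)
            bp5 = Breakpoint(contig, pos5, "five_prime")
            bp3 = Breakpoint(g3.contig, _sample_position(rng, truth, g3, "3p", "exonic"), "three_prime")
        elif cls == "pre-start-3p":
            bp5 = Breakpoint(g5.contig, _sample_position(rng, truth, g5, "5p", "exonic"), "five_prime")
            bp3 = Breakpoint(g3.contig, _sample_position(rng, truth, g3, "3p", cls), "three_prime")
        else:
            bp5 = Breakpoint(g5.contig, _sample_position(rng, truth, g5, "5p", cls), "five_prime")
            bp3 = Breakpoint(g3.contig, _sample_position(rng, truth, g3, "3p", "exonic"), "three_prime")
        fusion = FusionInput(bp5=bp5, bp3=bp3, source_row=i)
        cases.append(
            FusionTruth(
                fusion=fusion,
                fusion_class=cls,
                expected=oracle_candidates(truth, bp5, bp3),
            )
        )
    return cases


def write_generic_tsv(cases: list[FusionTruth], path, labeled: bool = False) -> None:
    with open(path, "w") as fh:
        for c in cases:
            row = [
                c.fusion.bp5.contig,
                str(c.fusion.bp5.position),
                c.fusion.bp3.contig,
                str(c.fusion.bp3.position),
            ]
            if labeled:
                row.append(str(c.label))
            fh.write("\t".join(row) + "\n")


def write_caller_tsv(cases: list[FusionTruth], path) -> None:
    """STAR-Fusion-style emission from the same truth table."""
    with open(path, "w") as fh:
        fh.write("#FusionName\tJunctionReadCount\tSpanningFragCount\tLeftBreakpoint\tRightBreakpoint\n")
        for i, c in enumerate(cases):
            fh.write(
                "\t".join(
                    [
                        f"fusion{i}",
                        str(10 + i),
                        str(5 + i),
                        f"{c.fusion.bp5.contig}:{c.fusion.bp5.position}:+",
                        f"{c.fusion.bp3.contig}:{c.fusion.bp3.position}:+",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# labeled motif datasets

def _random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


def make_labeled_sequences(
    n: int,
    motif: str,
    pos_fraction: float = 0.5,
    length_range: tuple[int, int] = (50, 180),
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Labeled amino-acid sequences: positives carry the motif, negatives don't.

    The motif is inserted at a uniformly random valid offset in positives;
    negatives are rejection-sampled until motif-free.
    """
    if not 0.0 < pos_fraction < 1.0:
        raise SynthError(f"pos_fraction must be in (0, 1), got {pos_fraction}")
    if len(motif) < 4:
        raise SynthError(f"motif must be at least 4 residues, got {len(motif)}")
    bad = set(motif) - set(AMINO_ACIDS)
    if bad:
        raise SynthError(f"motif contains invalid residues {sorted(bad)}")
    rng = random.Random(seed)
    n_pos = round(n * pos_fraction)
    labels = [1] * n_pos + [0] * (n - n_pos)
    rng.shuffle(labels)
    out = []
    for lab in labels:
        length = rng.randint(*length_range)
        if lab == 1:
            seq = _random_protein(rng, length)
            k = rng.randint(0, length - len(motif))
            seq = seq[:k] + motif + seq[k + len(motif) :]
        else:
            while True:
                seq = _random_protein(rng, length)
                if motif not in seq:
                    break
        out.append((seq, lab))
    return out


def _encode_protein(rng: random.Random, aa_seq: str) -> str:
    return "".join(rng.choice(AA_TO_CODONS[aa]) for aa in aa_seq)


def make_labeled_breakpoints(
    n: int,
    motif: str,
    pos_fraction: float = 0.5,
    length_range: tuple[int, int] = (40, 120),
    seed: int = 0,
) -> tuple[GenomeTruth, list[FusionTruth]]:
    """Breakpoint-backed labeled dataset on a purpose-built genome.

    Each labeled fusion joins a dedicated gene pair at codon boundaries so
    the single fused protein is exactly ``M`` + a designed sequence that
    contains (label 1) or lacks (label 0) the motif.
    """
    seqs = []
    rng = random.Random(seed + 1)
    for seq, lab in make_labeled_sequences(n, motif, pos_fraction, length_range, seed):
        # the fused protein will be 'M' + seq; keep negatives motif-free
        while lab == 0 and motif in "M" + seq:
            seq = _random_protein(rng, len(seq))
        seqs.append((seq, lab))

    contig = "chrS1"
    parts: list[str] = []
    pos = 0
    genes: list[GeneTruth] = []
    cases: list[FusionTruth] = []
    utr = 6

    def _add_gene(idx: int, aa_body: str) -> tuple[GeneTruth, TranscriptTruth]:
        nonlocal pos
        gap = rng.randint(30, 60)
        parts.append(_random_nt(rng, gap))
        pos += gap
        cds = "ATG" + _encode_protein(rng, aa_body) + rng.choice(STOPS)
        mrna = _random_nt(rng, utr) + cds + _random_nt(rng, utr)
        start = pos + 1
        gene_id = f"LBLG{idx:04d}"
        tx = TranscriptTruth(
            transcript_id=f"{gene_id}.T1",
            gene_id=gene_id,
            contig=contig,
            strand="+",
            mrna=mrna,
            utr5_len=utr,
            cds_len=len(cds),
            protein="M" + aa_body,
            exon_map=[(1, len(mrna), start, start + len(mrna) - 1)],
        )
        parts.append(mrna)
        pos += len(mrna)
        gene = GeneTruth(
            gene_id=gene_id,
            name=f"LBL{idx}",
            contig=contig,
            strand="+",
            span=(start, pos),
            transcripts=[tx],
        )
        genes.append(gene)
        return gene, tx

    for i, (seq, lab) in enumerate(seqs):
        p = rng.randint(1, len(seq) - 1)
        prefix, suffix = seq[:p], seq[p:]
        tail5 = _random_protein(rng, rng.randint(5, 15))
        lead3 = _random_protein(rng, rng.randint(2, 8))
        _g5, tx5 = _add_gene(2 * i + 1, prefix + tail5)
        _g3, tx3 = _add_gene(2 * i + 2, lead3 + suffix)
        # cut after the last prefix codon; resume at the first suffix codon
        bp5 = Breakpoint(contig, tx5.genomic_pos(tx5.utr5_len + 3 * (1 + p)), "five_prime")
        m3 = tx3.utr5_len + 3 * (1 + len(lead3)) + 1
        bp3 = Breakpoint(contig, tx3.genomic_pos(m3), "three_prime")
        fusion = FusionInput(bp5=bp5, bp3=bp3, source_row=i)
        cases.append(
            FusionTruth(
                fusion=fusion,
                fusion_class="exonic",
                expected=[
                    {
                        "gene5_id": tx5.gene_id,
                        "gene3_id": tx3.gene_id,
                        "candidates": [
                            {
                                "sequence": "M" + seq,
                                "tx5_id": tx5.transcript_id,
                                "tx3_id": tx3.transcript_id,
                                "truncated": False,
                                "in_frame": True,
                            }
                        ],
                        "reason": "",
                    }
                ],
                label=lab,
            )
        )
    parts.append(_random_nt(rng, 40))
    spec = GenomeSpec(n_contigs=1, genes_per_contig=max(1, 2 * n), seed=seed)
    truth = GenomeTruth(contigs={contig: "".join(parts)}, genes=genes, spec=spec)
    return truth, cases
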