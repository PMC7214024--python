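"""Genome and gene-annotation store with strand-aware queries.

Loads a FASTA genome and an Ensembl-dialect GTF into in-memory models and
answers the two queries fusion reconstruction needs: which genes overlap a
genomic position, and the spliced exon/CDS sequence of a transcript in
transcript orientation.

Coordinates are 1-based inclusive throughout, matching GTF.  The stop codon
is merged into the stored CDS intervals when the GTF follows the Ensembl
convention of excluding it, so the spliced CDS of a complete transcript ends
with a stop codon and translation can see it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import AnnotationError, GenomeError

Interval = tuple[int, int]  # 1-based inclusive (start, end), start <= end

_VALID_NT = set("ACGTN")
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GenomeSequence:
    """Uppercase nucleotide sequences keyed by contig name."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs = contigs

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sub-sequence for a 1-based inclusive interval; out-of-range is an error."""
        if contig not in self.contigs:
            raise GenomeError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise GenomeError(
                f"interval {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    strand: str  # '+' or '-'
    contig: str = ""
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)  # stop codon included
    has_annotated_start: bool = False
    has_annotated_stop: bool = False
    biotype: str = ""

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_span(self) -> Interval:
        return (self.cds[0][0], self.cds[-1][1])

    def start_codon_genomic(self) -> Interval:
        """Genomic interval of the first CDS codon (transcript orientation)."""
        if self.strand == "+":
            s = self.cds[0][0]
            return (s, s + 2)
        e = self.cds[-1][1]
        return (e - 2, e)

    def stop_codon_genomic(self) -> Interval:
        """Genomic interval of the last CDS codon (the stop, when annotated)."""
        if self.strand == "+":
            e = self.cds[-1][1]
            return (e - 2, e)
        s = self.cds[0][0]
        return (s, s + 2)


@dataclass
class GeneModel:
    gene_id: str
    name: str
    description: str
    strand: str
    contig: str
    span: Interval
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.is_coding]


class AnnotationIndex:
    """Genes indexed for (contig, position) lookup."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: g.gene_id)
        self._by_id = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        self._contigs: set[str] = set()
        for g in genes:
            self._contigs.add(g.contig)
            tree = self._trees.setdefault(g.contig, IntervalTree())
            # intervaltree is half-open; our coordinates are inclusive
            tree[g.span[0] : g.span[1] + 1] = g.gene_id
        self.n_skipped_contigs = 0
        self.n_invalid_transcripts = 0

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_at(self, contig: str, position: int) -> list[GeneModel]:
        """All genes whose span contains ``position``, sorted by gene_id."""
        if contig not in self._contigs:
            raise AnnotationError(f"unknown contig {contig!r}")
        hits = self._trees[contig][position]
        return sorted((self._by_id[h.data] for h in hits), key=lambda g: g.gene_id)


def load_genome(fasta_path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased and U is mapped to T.  Duplicate contig names
    are an error.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise GenomeError(f"duplicate contig {rec.id!r} in {fasta_path}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_NT
        if bad:
            raise GenomeError(f"contig {rec.id!r} has invalid characters {sorted(bad)}")
        contigs[rec.id] = seq
    if not contigs:
        raise GenomeError(f"no FASTA records in {fasta_path}")
    return GenomeSequence(contigs)


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Sort and merge touching/overlapping 1-based inclusive intervals."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def load_annotation(gtf_path, genome: GenomeSequence) -> AnnotationIndex:
    """Parse an Ensembl-dialect GTF into an :class:`AnnotationIndex`.

    Assembles transcripts from exon/CDS/start_codon/stop_codon features.
    Transcripts on contigs absent from ``genome`` are skipped (counted);
    transcripts whose CDS falls outside their exons are excluded (counted).
    """
    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}

    with open(gtf_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            contig, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if strand not in "+-":
                raise AnnotationError(f"{gtf_path}: line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{gtf_path}: line {lineno}: missing gene_id attribute")

            if feature == "gene":
                gene_rows[gene_id] = {
                    "contig": contig,
                    "strand": strand,
                    "span": (start, end),
                    "name": attrs.get("gene_name", gene_id),
                    "description": attrs.get("description", ""),
                }
                continue

            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                continue  # feature kinds below all require a transcript
            row = tx_rows.setdefault(
                tx_id,
                {
                    "gene_id": gene_id,
                    "contig": contig,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "start_codon": [],
                    "stop_codon": [],
                    "biotype": attrs.get("transcript_biotype", ""),
                },
            )
            if feature == "exon":
                row["exons"].append((start, end))
            elif feature == "CDS":
                row["cds"].append((start, end))
            elif feature in ("start_codon", "stop_codon"):
                row[feature].append((start, end))
            # transcript rows and unknown features carry no intervals we need

    genes: dict[str, GeneModel] = {}
    n_skipped_contigs = 0
    n_invalid = 0
    for gid, info in gene_rows.items():
        genes[gid] = GeneModel(
            gene_id=gid,
            name=info["name"],
            description=info["description"],
            strand=info["strand"],
            contig=info["contig"],
            span=info["span"],
        )

    for tx_id in sorted(tx_rows):
        row = tx_rows[tx_id]
        if row["contig"] not in genome:
            n_skipped_contigs += 1
            continue
        exons = sorted(row["exons"])
        cds = _merge_intervals(row["cds"] + row["stop_codon"])
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=row["gene_id"],
            strand=row["strand"],
            contig=row["contig"],
            exons=exons,
            cds=cds,
            biotype=row["biotype"],
        )
        if not exons:
            n_invalid += 1
            continue
        if cds and not all(
            any(es <= cs and ce <= ee for es, ee in exons) for cs, ce in cds
        ):
            n_invalid += 1
            continue
        if cds:
            if row["start_codon"]:
                tx.has_annotated_start = True
            else:
                tx.has_annotated_start = spliced_sequence(tx, genome, "cds")[:3] == "ATG"
            if row["stop_codon"]:
                tx.has_annotated_stop = True
            else:
                tx.has_annotated_stop = spliced_sequence(tx, genome, "cds")[-3:] in (
                    "TAA",
                    "TAG",
                    "TGA",
                )
        gid = row["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid,
                name=gid,
                description="",
                strand=row["strand"],
                contig=row["contig"],
                span=tx.span,
            )
        gene = genes[gid]
        gene.span = (min(gene.span[0], tx.span[0]), max(gene.span[1], tx.span[1]))
        gene.transcripts.append(tx)

    kept = [g for g in genes.values() if g.contig in genome]
    n_skipped_contigs += len(genes) - len(kept)
    index = AnnotationIndex(kept)
    index.n_skipped_contigs = n_skipped_contigs
    index.n_invalid_transcripts = n_invalid
    return index


def spliced_sequence(tx: TranscriptModel, genome: GenomeSequence, which: str = "exons") -> str:
    """Spliced transcript ('exons') or CDS ('cds') sequence, transcript orientation.

    Intervals are concatenated in genomic order and the whole block is
    reverse-complemented for minus-strand transcripts.
    """
    if which == "exons":
        ivs = tx.exons
    elif which == "cds":
        ivs = tx.cds
    else:
        raise ValueError(f"which must be 'exons' or 'cds', got {which!r}")
    # fetch() errors on out-of-range intervals, satisfying the error contract
    seq = "".join(genome.fetch(tx.contig, s, e) for s, e in ivs)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
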