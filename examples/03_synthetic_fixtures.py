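"""Generate a complete synthetic fixture set and verify it round-trips.

Writes a mini-genome (FASTA + GTF + JSON truth), a generic N x 4 breakpoint
file and the matching caller-style file, then re-parses everything with the
package's own loaders and prints the bookkeeping.
"""

import pathlib
import tempfile

from fusionprior import load_annotation, load_genome, parse_caller, parse_generic
from fusionprior.synth import (
    GenomeSpec,
    make_fusions,
    make_genome,
    write_caller_tsv,
    write_generic_tsv,
)

out = pathlib.Path(tempfile.mkdtemp())
spec = GenomeSpec(n_contigs=2, genes_per_contig=5, transcripts_per_gene=(1, 3), seed=11)
truth = make_genome(spec)
truth.write_fasta(out / "genome.fa")
truth.write_gtf(out / "annotation.gtf")
truth.write_truth_json(out / "truth.json")

cases = make_fusions(truth, 12, classes=("exonic", "intronic", "intergenic"), seed=11)
write_generic_tsv(cases, out / "fusions.tsv")
write_caller_tsv(cases, out / "fusions_star.tsv")

genome = load_genome(out / "genome.fa")
index = load_annotation(out / "annotation.gtf", genome)
print(f"genome: {len(genome.contigs)} contigs, "
      f"{sum(len(s) for s in genome.contigs.values())} bp")
print(f"annotation: {len(index.genes)} genes, "
      f"{sum(len(g.transcripts) for g in index.genes)} transcripts "
      f"({index.n_invalid_transcripts} invalid, {index.n_skipped_contigs} off-contig)")

generic = parse_generic(out / "fusions.tsv")
caller = parse_caller(out / "fusions_star.tsv", "star-fusion")
same = all(
    (a.bp5.contig, a.bp5.position, a.bp3.contig, a.bp3.position)
    == (b.bp5.contig, b.bp5.position, b.bp3.contig, b.bp3.position)
    for a, b in zip(generic, caller)
)
print(f"fusion files: {len(generic)} rows; generic == caller breakpoints: {same}")
print(f"fixture files written to {out}")

# The same truth table drives both emission formats, so the generic and the
# caller-style files must parse to identical breakpoint lists — the adapter
# equivalence the inference CLI relies on.
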