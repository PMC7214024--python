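"""Reconstruct candidate fused proteins from a pair of breakpoints.

Builds a small synthetic genome with known transcripts, picks one exonic
fusion case, and prints every candidate protein the breakpoint pair can
produce, with its junction and flag metadata.
"""

import pathlib
import tempfile

from fusionprior import enumerate_candidates, load_annotation, load_genome
from fusionprior.synth import GenomeSpec, make_fusions, make_genome

tmp = pathlib.Path(tempfile.mkdtemp())
spec = GenomeSpec(n_contigs=1, genes_per_contig=6, transcripts_per_gene=(1, 3), seed=3)
truth = make_genome(spec)
truth.write_fasta(tmp / "genome.fa")
truth.write_gtf(tmp / "annotation.gtf")

genome = load_genome(tmp / "genome.fa")
index = load_annotation(tmp / "annotation.gtf", genome)

case = make_fusions(truth, 1, classes=("exonic",), seed=4)[0]
bp5, bp3 = case.fusion.bp5, case.fusion.bp3
print(f"fusion: 5' {bp5.contig}:{bp5.position}  ->  3' {bp3.contig}:{bp3.position}")

for cset in enumerate_candidates(case.fusion, index, genome):
    print(f"gene pair {cset.gene5.name}_{cset.gene3.name} "
          f"({cset.gene5.gene_id} -> {cset.gene3.gene_id}), "
          f"{len(cset.proteins)} candidate protein(s)")
    for p in cset.proteins:
        flags = []
        if p.truncated:
            flags.append("truncated")
        if p.in_frame:
            flags.append("in-frame")
        if p.five_prime_complete:
            flags.append("5p-complete")
        if p.three_prime_complete:
            flags.append("3p-complete")
        print(f"  {p.tx5_id} x {p.tx3_id}: {len(p.sequence)} aa, "
              f"junction at residue {p.junction_aa} [{', '.join(flags) or 'none'}]")
        print(f"    {p.sequence[:60]}{'...' if len(p.sequence) > 60 else ''}")

# Each line is one coding-transcript pair: the protein is the 5' transcript
# translated from its ATG through the breakpoint, continued with the 3'
# transcript until the first stop codon.  "truncated" means that stop is
# not the downstream gene's own stop codon.
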