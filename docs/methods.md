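# Methods

## Problem and workflow

A gene fusion joins the 5' part of one gene (the upstream, promoter-donating
partner) to the 3' part of another. Whether a detected fusion drives an
oncogenic process or is a passenger event is not decided by the detection
step; this package prioritizes fusions downstream of any caller using only
the amino-acid sequence of the chimeric protein.

Given a pair of genomic breakpoints, the workflow is:

1. Resolve the genes overlapping each breakpoint and, for every pair of
   coding transcripts (one per partner), reconstruct the candidate fused
   transcript and translate it into a protein.
2. Score every candidate protein with a learned classifier emitting a value
   in [0, 1].
3. Aggregate per fusion by the **maximum** candidate score — a single
   high-scoring isoform pair is enough to flag the fusion — giving the
   fusion's oncogenic probability.
4. Sort fusions by probability and keep those `>= thr` (default 0.8) as the
   relevant set. Both the full ranked report and the thresholded view are
   produced; fusions for which no protein can be built carry `NA` and sort
   after all scored rows.

## Breakpoint and junction semantics

The input gives one coordinate per partner. The package interprets the 5'
coordinate as the **last genomic base retained** from the upstream gene and
the 3' coordinate as the **first genomic base retained** from the
downstream gene, both read in transcript orientation — the dominant
convention among fusion callers. Derived rules:

- **Intronic breakpoints** retain the exons wholly on the kept side; the
  breakpoint never creates novel exonic sequence, because the fusion
  transcript is a spliced product.
- Translation always begins at the 5' transcript's annotated ATG. If the 5'
  breakpoint falls upstream of the start codon the pair is skipped with
  reason `no_cds_retained_5p` (no downstream-ATG rescue is attempted);
  likewise a 3' breakpoint past the downstream stop codon is
  `no_cds_retained_3p`. Skips are counted per candidate set.
- Mid-codon cuts are allowed; the junction codon mixes bases from both
  genes, which is required to model frameshifts.
- The fused sequence is translated codon by codon with the standard genetic
  code until the first stop; codons containing N become X.

Per-candidate flags:

- `truncated` — the stop reached is **not** the downstream transcript's
  annotated stop codon (an early stop occurs in the protein), or no stop is
  reached at all.
- `five_prime_complete` — the retained 5' portion includes the upstream
  transcript's stop codon.
- `three_prime_complete` — the retained 3' portion includes the downstream
  transcript's start codon.
- `in_frame` — the first retained base of the downstream CDS is translated
  in its native codon phase (this generalizes the codon-boundary case to
  compensating mid-codon cuts).
- `junction_aa` — 1-based index of the first residue encoded fully or
  partly by the downstream gene; `length + 1` when translation stops
  earlier.

Candidates within a (gene5, gene3) pair are deduplicated by sequence and
ordered by (tx5_id, tx3_id), so output is deterministic. When breakpoints
hit overlapping genes, every (gene5, gene3) combination is reported as its
own row. The report's "main protein" is the top-scoring candidate, ties
broken by longer sequence then lexicographic transcript ids.

Coordinates are 1-based inclusive throughout (GTF native). The annotation
loader follows the Ensembl GTF dialect; because Ensembl excludes the stop
codon from CDS features, stop_codon intervals are merged into the stored
CDS so translation sees the terminal stop and the completeness flags can be
decided from sequence.

## The classifier

The scoring model is a small sequence network over index-encoded residues
(alphabet: the 20 standard amino acids plus X, which doubles as the
unknown-residue code; pad token 0; tail padding; truncation beyond
`max_len`):

    embedding (16) -> 1-D convolution (64 filters, kernel 7, same padding,
    ReLU) -> temporal max-pooling (width 4) -> bidirectional LSTM (64 units
    per direction, final states concatenated) -> dropout 0.3 -> dense
    sigmoid head

It is implemented directly in NumPy — explicit forward and backward passes
(including backpropagation through time for both LSTM directions) and an
Adam optimizer — so scoring and retraining are fully deterministic under a
seed and run on any CPU. A finite-difference gradient check of every
parameter block is part of the development validation. Defaults
(`ModelConfig`): learning rate 1e-3, batch 32, up to 20 epochs, early
stopping on validation loss with patience 5, `max_len` 1500. Index
embedding was chosen over one-hot because it is smaller and standard in
front of an embedding layer. All values are overridable per run.

Model archives are single HDF5 files holding every weight tensor plus the
JSON-serialized encoder and model configuration; loading an archive and
scoring is bit-reproducible.

## Retraining

Labels live on fusions (0 = not oncogenic, 1 = oncogenic) but the model
trains on sequences, so every candidate protein of a labeled fusion
inherits the fusion's label. Duplicate sequences are collapsed; a sequence
seen with both labels is dropped and counted rather than arbitrated.
Classes are balanced by seeded down-sampling of the majority class (no
synthetic duplication), mirroring the equally-balanced design of the
reference training corpus. The split is 80/20 stratified by label, seeded.
Training minimum is 20 examples. Retraining starts from fresh weights; a
warm start from an existing archive is available but not the default.

## Synthetic data

The generator emulates the tool's three inputs at miniature scale so the
full workflow is testable in seconds:

- **Mini-genomes** (`make_genome`): 1–2 contigs of a few kilobases,
  genes with 1–3 transcripts of 1–4 exons, CDS of 25–60 codons starting
  ATG, ending with a stop and free of internal in-frame stops (rejection
  sampling), UTRs of 3–30 nt, introns of 20–80 nt, intergenic gaps of
  60–150 nt, and a configurable strand mix (default half minus-strand).
  Additional isoforms skip a frame-preserving internal exon when one
  exists without introducing a premature stop; otherwise they replicate the
  primary structure under a new id, which exercises candidate
  deduplication. Truth tables record every transcript's mRNA, protein and
  exon map.
- **Fusion cases** (`make_fusions`): breakpoints sampled per class —
  exonic, intronic, 5'-UTR, post-stop on the 5' side, pre-start on the 3'
  side, intergenic — with expected proteins and flags computed by a naive
  oracle that splices plain mRNA strings and translates with an explicit
  codon dictionary. The oracle shares no code with the fusion builder
  (different coordinate bookkeeping, different translation table), so
  exact agreement between the two is a meaningful check.
- **Labeled datasets** (`make_labeled_sequences` /
  `make_labeled_breakpoints`): random proteins in which a discriminative
  motif (length >= 4) is planted at a uniform random offset in positives
  and rejection-excluded from negatives; optionally backed by a
  purpose-built genome plus an N x 5 breakpoint file whose single fused
  protein per row carries or lacks the motif according to the label.

What the generator does **not** emulate: realistic gene length, GC and
codon-usage distributions, alternative promoters, overlapping genes (a
hand-written overlapping-locus fixture covers that query path), sequencing
noise, and real oncogenic sequence signal. Passing tests therefore
demonstrate the correctness of reconstruction, bookkeeping and the learning
machinery — not that the default model recognizes real driver fusions; for
real use the model must be trained on curated fusion proteins.

## Validation design and numerical choices

- **Reconstruction**: 600 randomized fusion cases (5 genome seeds x 120
  cases across all breakpoint classes) must match the string oracle
  exactly — sequence, junction index and all four flags.
- **Learnability**: on a planted-motif dataset (n = 600, balanced, motif
  length 6, `max_len` 200) the model must reach held-out AUROC >= 0.9
  within 20 epochs on one CPU. The chance-level control retrains on
  label-shuffled copies of the same data. With the 80/20 split the
  validation set has 120 sequences, so a single null AUROC has a standard
  deviation of about 0.053 and a single draw is an imprecise estimate of
  chance level; the control statistic is therefore the mean validation
  AUROC over three independent label permutations (SD about 0.03), which
  must lie in [0.4, 0.6]. Problem sizes here are chosen so the whole
  validation runs in minutes on one CPU.
- **Numerics**: scores are probabilities from a sigmoid, clipped only
  inside the cross-entropy (eps 1e-12); archive round trips are checked to
  1e-6; ranking ties are broken by input order (stable sort) for
  reproducibility; the probability is printed with two decimals in the
  report while the full precision is kept in memory.
- **Degenerate inputs**: empty candidate sets are reported with a reason
  code and `NA` probability rather than an error; empty sequences cannot be
  encoded; fusions shorter than one codon are skipped as `too_short`;
  translation that stops at the very first codon is skipped as
  `empty_protein` (a protein must have at least one residue).

## Known limitations

- Only the Ensembl GTF dialect is supported (no GFF3, no chromosome-name
  aliasing beyond what the user provides).
- One caller adapter ships (STAR-Fusion-style columns); the registry in
  `io_tabular.CALLER_FORMATS` makes further adapters a data-only change.
- No downstream-ATG rescue for 5'-UTR breakpoints; such transcript pairs
  are skipped and counted.
- Non-canonical genetic codes, selenocysteine and read-through fusions are
  out of scope.
- The NumPy trainer is single-threaded by design; it is sized for the
  package's retraining-scale datasets (thousands of sequences), not for
  corpus-scale pretraining.
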