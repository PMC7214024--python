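"""End-to-end inference: breakpoints -> candidate proteins -> ranked report."""

from __future__ import annotations

from .annotation import AnnotationIndex, GenomeSequence
from .fusions import FusionCandidateSet, FusionInput, enumerate_candidates
from .io_tabular import FusionResult
from .model import PredictionModel, ThresholdPolicy, aggregate, score_candidates, sort_results


def _result_for_set(cset: FusionCandidateSet, model: PredictionModel) -> FusionResult:
    g5, g3 = cset.gene5, cset.gene3
    pair = f"{g5.name}_{g3.name}" if g5 and g3 else "NA_NA"
    base = FusionResult(
        fusion_pair=pair,
        onc_prob=None,
        gene5_id=g5.gene_id if g5 else "",
        gene5_name=g5.name if g5 else "",
        gene5_description=g5.description if g5 else "",
        gene3_id=g3.gene_id if g3 else "",
        gene3_name=g3.name if g3 else "",
        gene3_description=g3.description if g3 else "",
        n_candidates=len(cset.proteins),
        reason=cset.reason,
        source_row=cset.fusion.source_row,
    )
    if not cset.proteins:
        return base
    scores = score_candidates(model, cset)
    base.onc_prob = aggregate(scores)
    # main protein: the top-scoring candidate; ties broken by longer
    # sequence, then lexicographic (tx5_id, tx3_id)
    order = sorted(
        range(len(cset.proteins)),
        key=lambda i: (
            -scores[i],
            -len(cset.proteins[i].sequence),
            cset.proteins[i].tx5_id,
            cset.proteins[i].tx3_id,
        ),
    )
    main = cset.proteins[order[0]]
    base.main_protein = main.sequence
    base.main_protein_length = len(main.sequence)
    base.truncated = main.truncated
    base.five_prime_complete = main.five_prime_complete
    base.three_prime_complete = main.three_prime_complete
    return base


def run_inference(
    fusions: list[FusionInput],
    index: AnnotationIndex,
    genome: GenomeSequence,
    model: PredictionModel,
    policy: ThresholdPolicy | None = None,
) -> tuple[list[FusionResult], list[FusionResult]]:
    """Score and rank fusions.

    Returns ``(full_report, relevant)``: every (gene5, gene3) pair of every
    input fusion sorted by non-increasing probability with NA rows last, and
    the thresholded view (probability >= thr, NA rows excluded).
    """
    policy = policy or ThresholdPolicy()
    results = []
    for fusion in fusions:
        for cset in enumerate_candidates(fusion, index, genome):
            results.append(_result_for_set(cset, model))
    full = sort_results(results)
    relevant = [r for r in full if r.onc_prob is not None and r.onc_prob >= policy.thr]
    return full, relevant
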