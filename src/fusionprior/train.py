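"""Retraining: labeled breakpoints -> balanced protein dataset -> new model.

Every candidate protein of a labeled fusion inherits the fusion's 0/1
oncogenicity label.  Duplicate sequences are collapsed; sequences observed
with both labels are dropped (counted, not arbitrated).  The majority class
is down-sampled to balance, mirroring the equally-balanced design of the
reference training set, and a fresh CNN->biLSTM model is trained with
binary cross-entropy, a stratified 80/20 validation split and early
stopping on validation loss.  The resulting archive is loadable by the
inference layer and reproduces the trainer's validation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

from .annotation import AnnotationIndex, GenomeSequence
from .errors import FusionPriorError
from .fusions import enumerate_candidates
from .io_tabular import LabeledFusionInput
from .model import EncoderConfig, ModelConfig, PredictionModel, build_model, encode_batch

MIN_EXAMPLES = 20


@dataclass
class TrainingDataset:
    examples: list[tuple[str, int, str]]  # (sequence, label, provenance fusion id)
    seed: int = 0
    val_fraction: float = 0.2
    n_conflicts: int = 0  # sequences dropped for appearing with both labels

    def class_counts(self) -> tuple[int, int]:
        labels = [lab for _, lab, _ in self.examples]
        return labels.count(0), labels.count(1)


@dataclass
class TrainingReport:
    epochs_run: int
    final_train_loss: float
    val_accuracy: float
    val_auroc: float
    counts_before_balancing: tuple[int, int]
    counts_after_balancing: tuple[int, int]
    n_conflicts: int
    seed: int
    config: dict = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def build_training_set(
    labeled: list[LabeledFusionInput],
    index: AnnotationIndex,
    genome: GenomeSequence,
    seed: int = 0,
) -> TrainingDataset:
    """Expand labeled fusions into labeled candidate-protein sequences."""
    by_seq: dict[str, tuple[int, str]] = {}
    conflicts: set[str] = set()
    for rec in labeled:
        if rec.label not in (0, 1):
            raise FusionPriorError(f"label must be 0 or 1, got {rec.label}")
        fid = (
            f"{rec.fusion.bp5.contig}:{rec.fusion.bp5.position}"
            f"_{rec.fusion.bp3.contig}:{rec.fusion.bp3.position}"
        )
        for cset in enumerate_candidates(rec.fusion, index, genome):
            for prot in cset.proteins:
                seq = prot.sequence
                if seq in conflicts:
                    continue
                if seq in by_seq and by_seq[seq][0] != rec.label:
                    del by_seq[seq]
                    conflicts.add(seq)
                elif seq not in by_seq:
                    by_seq[seq] = (rec.label, fid)
    if not by_seq:
        raise FusionPriorError("empty training set: no candidate protein could be built")
    examples = sorted(
        ((seq, lab, fid) for seq, (lab, fid) in by_seq.items()),
        key=lambda e: (e[2], e[0]),
    )
    return TrainingDataset(examples=examples, seed=seed, n_conflicts=len(conflicts))


def balance(ds: TrainingDataset, seed: int | None = None) -> TrainingDataset:
    """Down-sample the majority class so class counts differ by at most 1."""
    seed = ds.seed if seed is None else seed
    neg = [e for e in ds.examples if e[1] == 0]
    pos = [e for e in ds.examples if e[1] == 1]
    if not neg or not pos:
        raise FusionPriorError("balancing needs both classes present")
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        keep = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(keep)]
    elif len(pos) > len(neg):
        keep = rng.choice(len(pos), size=len(neg), replace=False)
        pos = [pos[i] for i in sorted(keep)]
    merged = sorted(neg + pos, key=lambda e: (e[2], e[0]))
    return TrainingDataset(
        examples=merged, seed=ds.seed, val_fraction=ds.val_fraction, n_conflicts=ds.n_conflicts
    )


def _stratified_split(labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))


def train(
    ds: TrainingDataset,
    mcfg: ModelConfig | None = None,
    enc: EncoderConfig | None = None,
    counts_before: tuple[int, int] | None = None,
    warm_start: PredictionModel | None = None,
) -> tuple[PredictionModel, TrainingReport]:
    """Train a model on a balanced dataset; returns the model and a report."""
    mcfg = mcfg or ModelConfig()
    enc = enc or EncoderConfig()
    n0, n1 = ds.class_counts()
    if abs(n0 - n1) > 1:
        raise FusionPriorError(f"dataset not balanced: {n0} vs {n1} (run balance() first)")
    if len(ds.examples) < MIN_EXAMPLES:
        raise FusionPriorError(
            f"dataset too small: {len(ds.examples)} examples (minimum {MIN_EXAMPLES})"
        )

    seqs = [e[0] for e in ds.examples]
    labels = np.array([e[1] for e in ds.examples], dtype=np.float64)
    X = encode_batch(seqs, enc)
    split_rng = np.random.default_rng(ds.seed)
    train_idx, val_idx = _stratified_split(labels, ds.val_fraction, split_rng)
    Xtr, ytr = X[train_idx], labels[train_idx]
    Xva, yva = X[val_idx], labels[val_idx]

    model = warm_start or build_model(mcfg, enc, seed=mcfg.seed)
    net = model.net
    drop_rng = np.random.default_rng(mcfg.seed + 1)
    shuffle_rng = np.random.default_rng(mcfg.seed + 2)

    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = 0
    wait = 0
    history: list[dict] = []
    final_train_loss = np.nan
    epochs_run = 0
    for epoch in range(1, mcfg.epochs + 1):
        order = shuffle_rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(order), mcfg.batch_size):
            batch = order[start : start + mcfg.batch_size]
            loss, grads = net.loss_and_grads(Xtr[batch], ytr[batch], drop_rng)
            net.adam_step(grads, lr=mcfg.learning_rate)
            losses.append(loss)
        final_train_loss = float(np.mean(losses))
        val_probs = net.predict(Xva, batch_size=mcfg.batch_size)
        val_loss = _bce(val_probs, yva)
        history.append({"epoch": epoch, "train_loss": final_train_loss, "val_loss": val_loss})
        epochs_run = epoch
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = net.copy_params()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= mcfg.patience:
                break
    net.set_params(best_params)

    val_probs = net.predict(Xva, batch_size=mcfg.batch_size)
    val_acc = float(np.mean((val_probs >= 0.5) == (yva == 1)))
    try:
        val_auroc = float(roc_auc_score(yva, val_probs))
    except ValueError:  # single-class validation split
        val_auroc = float("nan")
    report = TrainingReport(
        epochs_run=epochs_run,
        final_train_loss=final_train_loss,
        val_accuracy=val_acc,
        val_auroc=val_auroc,
        counts_before_balancing=counts_before or (n0, n1),
        counts_after_balancing=(n0, n1),
        n_conflicts=ds.n_conflicts,
        seed=ds.seed,
        config={**asdict(mcfg), "max_len": enc.max_len, "best_epoch": best_epoch},
        history=history,
    )
    return model, report


def validation_scores(
    ds: TrainingDataset, model: PredictionModel
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels of the dataset's validation split under ``model``.

    Recomputes the same seeded split as :func:`train`, so a reloaded archive
    can be checked against the trainer's own validation scores.
    """
    labels = np.array([e[1] for e in ds.examples], dtype=np.float64)
    split_rng = np.random.default_rng(ds.seed)
    _, val_idx = _stratified_split(labels, ds.val_fraction, split_rng)
    seqs = [ds.examples[i][0] for i in val_idx]
    return model.score_batch(seqs), labels[val_idx]
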