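"""Scoring, aggregation, ranking: the prioritization layer.

Amino-acid sequences are index-encoded over the 20 standard residues plus
X (pad token 0, tail padding, tail truncation beyond ``max_len``) and scored
by the CNN->biLSTM network.  A fusion's oncogenic probability is the maximum
of its candidate-protein scores, so a single high-scoring candidate protein
is enough to rank the fusion as likely oncogenic.  Fusions are then sorted
by probability and filtered at a user threshold ``thr`` (default 0.8; rows
with probability >= thr are kept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import h5py
import numpy as np

from .errors import ModelError
from .fusions import FusionCandidateSet
from .io_tabular import FusionResult
from .nn import NeuralScorer

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ARCHIVE_FORMAT = "fusionprior-model-1"


@dataclass(frozen=True)
class EncoderConfig:
    max_len: int = 1500
    alphabet: str = AMINO_ACIDS + "X"  # X doubles as the unknown-residue token

    @property
    def vocab_size(self) -> int:
        return len(self.alphabet) + 1  # + pad token 0


@dataclass
class ModelConfig:
    embedding_dim: int = 16
    conv_filters: int = 64
    conv_kernel: int = 7
    pool_size: int = 4
    lstm_units: int = 64
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 20
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "embedding_dim",
            "conv_filters",
            "conv_kernel",
            "pool_size",
            "lstm_units",
            "learning_rate",
            "batch_size",
            "epochs",
        ):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class ThresholdPolicy:
    thr: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.thr <= 1.0:
            raise ModelError(f"threshold must be in [0, 1], got {self.thr}")


def encode(seq: str, cfg: EncoderConfig) -> np.ndarray:
    """Index-encode one sequence: residue -> alphabet index + 1, pad 0.

    Residues outside the alphabet map to X; sequences longer than
    ``max_len`` keep their first ``max_len`` residues.
    """
    if not seq:
        raise ModelError("cannot encode an empty sequence")
    idx = {aa: i + 1 for i, aa in enumerate(cfg.alphabet)}
    x_code = idx["X"]
    out = np.zeros(cfg.max_len, dtype=np.int64)
    for i, aa in enumerate(seq[: cfg.max_len]):
        out[i] = idx.get(aa, x_code)
    return out


def decode(vec: np.ndarray, cfg: EncoderConfig) -> str:
    """Inverse of :func:`encode` for unpadded, untruncated sequences."""
    return "".join(cfg.alphabet[i - 1] for i in vec if i > 0)


def encode_batch(seqs: list[str], cfg: EncoderConfig) -> np.ndarray:
    return np.stack([encode(s, cfg) for s in seqs])


class PredictionModel:
    """Encoder config + network weights + the score function."""

    def __init__(self, encoder: EncoderConfig, config: ModelConfig, net: NeuralScorer):
        self.encoder = encoder
        self.config = config
        self.net = net

    def score(self, sequence: str) -> float:
        return float(self.score_batch([sequence])[0])

    def score_batch(self, sequences: list[str]) -> np.ndarray:
        ids = encode_batch(sequences, self.encoder)
        return self.net.predict(ids, batch_size=self.config.batch_size)

    # -- archive -------------------------------------------------------
    def save(self, path) -> None:
        """Write the model archive: weights plus serialized configs (HDF5)."""
        with h5py.File(path, "w") as f:
            f.attrs["format"] = ARCHIVE_FORMAT
            f.attrs["encoder"] = json.dumps(asdict(self.encoder))
            f.attrs["config"] = json.dumps(asdict(self.config))
            g = f.create_group("weights")
            for k, v in self.net.params.items():
                g.create_dataset(k, data=v)

    @classmethod
    def load(cls, path) -> "PredictionModel":
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != ARCHIVE_FORMAT:
                raise ModelError(f"{path}: not a model archive (format attribute missing)")
            encoder = EncoderConfig(**json.loads(f.attrs["encoder"]))
            config = ModelConfig(**json.loads(f.attrs["config"]))
            weights = {k: np.asarray(v) for k, v in f["weights"].items()}
        model = build_model(config, encoder, seed=config.seed)
        model.net.set_params(weights)
        return model


def build_model(cfg: ModelConfig, enc: EncoderConfig, seed: int | None = None) -> PredictionModel:
    """Fresh (untrained) model with seeded weight initialization."""
    net = NeuralScorer(
        vocab_size=enc.vocab_size,
        max_len=enc.max_len,
        embedding_dim=cfg.embedding_dim,
        conv_filters=cfg.conv_filters,
        conv_kernel=cfg.conv_kernel,
        pool_size=cfg.pool_size,
        lstm_units=cfg.lstm_units,
        dropout=cfg.dropout,
        seed=cfg.seed if seed is None else seed,
    )
    return PredictionModel(encoder=enc, config=cfg, net=net)


def score_candidates(model: PredictionModel, cset: FusionCandidateSet) -> np.ndarray:
    """One score in [0, 1] per candidate protein of the set."""
    if not cset.proteins:
        raise ModelError("cannot score an empty candidate set")
    return model.score_batch([p.sequence for p in cset.proteins])


def aggregate(scores) -> float:
    """Per-fusion oncogenic probability: the maximum candidate score."""
    scores = list(scores)
    if not scores:
        raise ModelError("cannot aggregate an empty score list")
    if any(s < 0.0 or s > 1.0 for s in scores):
        raise ModelError("scores must lie in [0, 1]")
    return float(max(scores))


def sort_results(results: list[FusionResult]) -> list[FusionResult]:
    """Full-report order: scored rows by non-increasing probability (stable
    by source row on ties), then NA rows in input order."""
    scored = [r for r in results if r.onc_prob is not None]
    na = [r for r in results if r.onc_prob is None]
    scored.sort(key=lambda r: (-r.onc_prob, r.source_row))
    na.sort(key=lambda r: r.source_row)
    return scored + na


def rank_and_filter(results: list[FusionResult], policy: ThresholdPolicy) -> list[FusionResult]:
    """Ranked view of the fusions considered relevant: probability >= thr.

    NA rows (no buildable protein) are excluded from this view; they remain
    available in the full report.
    """
    ranked = [r for r in sort_results(results) if r.onc_prob is not None]
    return [r for r in ranked if r.onc_prob >= policy.thr]
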