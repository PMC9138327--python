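"""Loss, regularization and the training loop.

The objective is binary cross-entropy over the predicted interaction
probabilities plus an L2 penalty on the trainable weight matrices,
minimized with Adam over shuffled mini-batches. After every epoch the
model is scored on the validation partition by ROC-AUC and the weights
of the best-AUC epoch are kept (early stopping on a patience counter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .data import SplitDataset
from .encode import EncodedDataset, encode_records
from .evaluate import roc_auc_score
from .model import ModelConfig, MultiViewDTI
from .vocab import ScreenConfig, Vocabulary, build_drug_vocab, build_protein_vocab

logger = logging.getLogger(__name__)

PROB_EPS = 1e-7


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The defaults (Adam at 1e-3, batches of 64, up to 50 epochs with
    patience 10, lambda 1e-5) are conventional for sequence classifiers
    of this size; every value is configurable.
    """

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    l2_lambda: float | None = None  # None -> use ModelConfig.l2_lambda
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_lambda is not None and self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch training record; ``best_epoch`` maximizes validation AUC."""

    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmax(self.val_auc))

    @property
    def best_val_auc(self) -> float:
        return float(np.max(self.val_auc))


def bce_loss(labels, probabilities):
    """Mean binary cross-entropy, -(1/n) sum[y log p + (1-y) log(1-p)].

    Probabilities are clipped to [eps, 1-eps] (eps = 1e-7) before the
    logs. Accepts numpy arrays (returns a float) or Tensors (returns a
    scalar Tensor in the computation graph).
    """
    if isinstance(probabilities, Tensor):
        y = np.asarray(labels, dtype=np.float64)
        if y.shape != probabilities.shape:
            raise ValueError(f"shape mismatch: {y.shape} vs {probabilities.shape}")
        p = ag.clip(probabilities, PROB_EPS, 1.0 - PROB_EPS)
        terms = ag.mul_constant(ag.log(p), y) + ag.mul_constant(ag.log(1.0 - p), 1.0 - y)
        return -terms.mean()
    y = np.asarray(labels, dtype=np.float64)
    p = np.clip(np.asarray(probabilities, dtype=np.float64), PROB_EPS, 1.0 - PROB_EPS)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def l2_penalized_loss(base_loss, weights: Sequence, lam: float):
    """base_loss + lambda * sum of squared weight-matrix entries.

    Biases are excluded by the caller (pass weight matrices only).
    Works on Tensors (graph) or numpy arrays (float).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(base_loss, Tensor) or any(isinstance(w, Tensor) for w in weights):
        total = ag.as_tensor(base_loss)
        if lam > 0:
            for w in weights:
                total = total + lam * (ag.as_tensor(w) ** 2.0).sum()
        return total
    return float(base_loss) + lam * float(sum(np.sum(np.square(w)) for w in weights))


def build_vocabularies(
    split: SplitDataset,
    screen: ScreenConfig = ScreenConfig(),
    train_only: bool = False,
) -> tuple[Vocabulary, Vocabulary]:
    """Fit the protein and drug vocabularies on the split's sequences.

    By default all three partitions contribute, matching the reference
    protocol (the character alphabet of the evaluation drugs is then
    known at fit time); ``train_only=True`` restricts fitting to the
    training partition for a leakage-free variant.
    """
    records = list(split.train) if train_only else (
        list(split.train) + list(split.valid) + list(split.test)
    )
    proteins = sorted({r.sequence for r in records})
    smiles = sorted({r.smiles for r in records})
    return build_protein_vocab(proteins, screen), build_drug_vocab(smiles)


def _batch_order(enc: EncodedDataset, batch_size: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled mini-batches of similar protein length.

    Samples are ordered by real token length plus a random jitter and
    sliced into batches, and the batch order is shuffled. Batches of
    similar length keep the (length-trimmed) attention cost near the
    true sequence length instead of the batch maximum, while the jitter
    and batch shuffle preserve stochasticity.
    """
    lengths = (enc.protein_ids != 0).sum(axis=1).astype(np.float64)
    keys = lengths + rng.uniform(0.0, 12.0, size=len(enc))
    order = np.argsort(keys, kind="stable")
    batches = [order[s : s + batch_size] for s in range(0, len(enc), batch_size)]
    rng.shuffle(batches)
    return batches


def _epoch_loss(model: MultiViewDTI, enc: EncodedDataset,
                opt: Adam, lam: float, batch_size: int,
                rng: np.random.Generator, epoch: int) -> float:
    losses = []
    for idx in _batch_order(enc, batch_size, rng):
        probs = model.forward(enc.protein_ids[idx], enc.drug_ids[idx],
                              enc.fingerprints[idx], training=True, rng=rng)
        loss = l2_penalized_loss(bce_loss(enc.labels[idx], probs),
                                 model.weight_matrices(), lam)
        if not np.isfinite(loss.data):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return float(np.mean(losses))


def train_model(
    split: SplitDataset,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    vocabularies: tuple[Vocabulary, Vocabulary] | None = None,
) -> tuple[MultiViewDTI, TrainHistory]:
    """Train on the split; return the model at its best validation AUC.

    Vocabularies are fitted on the split if not supplied. The returned
    model carries the weights of the epoch whose validation AUC was
    highest; training stops early once that AUC has not improved for
    ``patience`` epochs.
    """
    if vocabularies is None:
        vocabularies = build_vocabularies(split)
    protein_vocab, drug_vocab = vocabularies
    enc_train = encode_records(split.train, protein_vocab, drug_vocab,
                               model_cfg.protein_length, model_cfg.drug_length)
    enc_valid = encode_records(split.valid, protein_vocab, drug_vocab,
                               model_cfg.protein_length, model_cfg.drug_length)
    model = MultiViewDTI(model_cfg, protein_vocab.embedding_rows, drug_vocab.embedding_rows)
    lam = train_cfg.l2_lambda if train_cfg.l2_lambda is not None else model_cfg.l2_lambda
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    history = TrainHistory()
    best_state = model.state_dict()
    best_auc = -np.inf
    stale = 0
    for epoch in range(train_cfg.epochs):
        mean_loss = _epoch_loss(model, enc_train, opt, lam,
                                train_cfg.batch_size, rng, epoch)
        val_scores = model.predict(enc_valid)
        val_auc = roc_auc_score(val_scores, enc_valid.labels)
        history.train_loss.append(mean_loss)
        history.val_auc.append(float(val_auc))
        logger.info("epoch %d: train loss %.4f, val AUC %.4f", epoch, mean_loss, val_auc)
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                logger.info("early stop at epoch %d (no AUC gain for %d epochs)",
                            epoch, train_cfg.patience)
                break
    model.load_state_dict(best_state)
    return model, history
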