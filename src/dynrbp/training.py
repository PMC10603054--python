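"""Optimization: regularized cross-entropy objective, Adam with linear
warm-up, early stopping on validation loss with best-checkpoint restore, and
ROC-AUC evaluation."""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .autograd import Tensor
from .dataset import FixedSample
from .model import BindingPredictor

logger = logging.getLogger(__name__)

EPS = 1e-7  # probability clamp in the loss

__all__ = ["TrainConfig", "TrainHistory", "bce_l2_loss", "bce_loss_from_logits",
           "train", "evaluate_auc", "fine_tune_cls"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.001
    weight_decay: float = 1e-6
    warmup_steps: Optional[int] = None  # default: one epoch of steps
    patience: int = 5
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_auc: List[float] = field(default_factory=list)
    lr_trace: List[float] = field(default_factory=list)  # per optimizer step
    stopped_epoch: int = 0
    best_epoch: int = 0


def bce_l2_loss(p: np.ndarray, y: np.ndarray,
                weights: Sequence[np.ndarray] = (),
                lam: float = 0.0) -> float:
    """Mean binary cross-entropy plus ``lam`` times the L2 norm of the
    parameters; probabilities are clamped away from {0, 1}."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=float)
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if lam:
        bce += lam * np.sqrt(sum(float((w ** 2).sum()) for w in weights))
    return float(bce)


def bce_loss_from_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Differentiable mean BCE from logits (numerically stable via the
    clamped-sigmoid formulation)."""
    p = logits.sigmoid().clip(EPS, 1.0 - EPS)
    y_t = Tensor(np.asarray(y, dtype=float))
    losses = -(y_t * p.log() + (1.0 - y_t) * (1.0 - p).log())
    return losses.mean()


def evaluate_auc(predictor_or_scores, test_set: Sequence[FixedSample] | None = None,
                 labels: Optional[np.ndarray] = None) -> float:
    """ROC-AUC: probability a random positive outscores a random negative
    (ties counted 1/2).

    Accepts either ``(predictor, samples)`` or ``(scores, labels=...)``.
    """
    if test_set is not None:
        labels = np.array([s.label for s in test_set])
        scores = predictor_or_scores.predict_proba(list(test_set))
    else:
        scores = np.asarray(predictor_or_scores, dtype=float)
        labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes in the test set")
    return float(roc_auc_score(labels, scores))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _eval_loss(predictor: BindingPredictor, samples: Sequence[FixedSample],
               batch_size: int) -> float:
    y = np.array([s.label for s in samples])
    p = predictor.predict_proba(list(samples), batch_size=batch_size)
    return bce_l2_loss(p, y)


def train(predictor: BindingPredictor, train_set: Sequence[FixedSample],
          val_set: Sequence[FixedSample], cfg: TrainConfig
          ) -> TrainHistory:
    """Adam with linear warm-up; early stop when validation loss fails to
    improve for ``cfg.patience`` epochs; restores the best-validation
    parameters in place.

    The L2 term of the objective is applied once, through the optimizer's
    weight decay, to avoid double regularization.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    params = predictor.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    steps_per_epoch = int(np.ceil(len(train_set) / cfg.batch_size))
    warmup = cfg.warmup_steps if cfg.warmup_steps is not None else steps_per_epoch
    history = TrainHistory()
    best_val = np.inf
    best_state = None
    since_best = 0
    step = 0

    modules = [predictor.model] + ([predictor.encoder]
                                   if hasattr(predictor.encoder, "train") else [])
    labels = np.array([s.label for s in train_set])

    for epoch in range(1, cfg.max_epochs + 1):
        for m in modules:
            m.train(True)
        epoch_losses = []
        for idx in _batches(len(train_set), cfg.batch_size, rng):
            step += 1
            opt.lr = cfg.learning_rate * min(1.0, step / warmup) if warmup \
                else cfg.learning_rate
            history.lr_trace.append(opt.lr)
            batch = [train_set[i] for i in idx]
            logits = predictor.forward_batch(batch)
            loss = bce_loss_from_logits(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        for m in modules:
            m.train(False)
        val_loss = _eval_loss(predictor, val_set, cfg.batch_size)
        try:
            val_auc = evaluate_auc(predictor, val_set)
        except ValueError:
            val_auc = float("nan")
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_auc.append(val_auc)
        history.stopped_epoch = epoch
        logger.info("epoch %d: train loss %.4f, val loss %.4f, val AUC %.4f",
                    epoch, history.train_loss[-1], val_loss, val_auc)
        if val_loss < best_val:
            best_val = val_loss
            best_state = [p.data.copy() for p in params]
            best_buffers = [(m, m.state_dict()) for m in modules]
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        for p, data in zip(params, best_state):
            p.data = data
        for m, state in best_buffers:
            m.load_state_dict(state)
    for m in modules:
        m.train(False)
    return history


def fine_tune_cls(encoder, samples: Sequence[FixedSample], cfg: TrainConfig,
                  epochs: int = 3, mask_rate: float = 0.0) -> List[float]:
    """Light classification fine-tuning of the encoder through a linear head
    on the [CLS] hidden state, so the [CLS] attention row becomes informative
    for motif calling.

    ``mask_rate`` randomly replaces that fraction of interior tokens with
    [UNK] during fine-tuning (BERT-style corruption), which forces the
    classifier to rely on several evidence tokens rather than a single one.
    Returns per-epoch losses.
    """
    rng = np.random.default_rng(cfg.seed)
    head = nn.Linear(encoder.d_model, 1, np.random.default_rng(cfg.seed + 1))
    params = encoder.parameters() + head.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    labels = np.array([s.label for s in samples])
    unk = encoder.vocab.unk_id
    losses = []
    encoder.train(True)
    for _ in range(epochs):
        epoch_losses = []
        for idx in _batches(len(samples), cfg.batch_size, rng):
            batch = [samples[i] for i in idx]
            ids = encoder.encode_ids([s.sequence for s in batch])
            if mask_rate > 0:
                mask = rng.random(ids.shape) < mask_rate
                mask[:, 0] = mask[:, -1] = False  # keep [CLS]/[SEP]
                ids = np.where(mask, unk, ids)
            hidden = encoder.forward(ids)  # (N, T, d)
            logits = head(hidden[:, 0, :]).reshape(len(batch))
            loss = bce_loss_from_logits(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        losses.append(float(np.mean(epoch_losses)))
    encoder.train(False)
    return losses
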