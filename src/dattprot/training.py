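"""Masked-LM pre-training, supervised fine-tuning, and evaluation metrics.

Pre-training follows the BERT-style recipe on amino-acid tokens: 15% of the
eligible (non-PAD, non-unknown) positions per sequence are selected; each is
masked with probability 0.8, replaced by a uniformly random residue token
with probability 0.1, or left unchanged with probability 0.1.  A position-wise
linear decoder predicts the original residue; the loss is the mean
cross-entropy over the selected positions.

Both phases minimize cross-entropy with AdamW.  Pre-training uses linear
warm-up followed by inverse-sqrt decay; fine-tuning starts at 1e-5 and decays
by a factor 0.95 every hundred iterations, with 1e-4 weight decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from . import optim
from .autograd import Tensor, log_softmax, no_grad
from .model import DAttProtModel
from .sequence_codec import TokenSequence, Vocabulary


class SkipRecord(Exception):
    """Signal: a record has no eligible positions for masked-LM corruption."""


@dataclass(frozen=True)
class PretrainConfig:
    mask_fraction: float = 0.15
    action_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)  # mask/random/keep
    warmup_steps: int = 50_000
    peak_lr: float = 5e-5
    max_epochs: int = 3
    batch_size: int = 32
    weight_decay: float = 1e-4

    def __post_init__(self):
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in (0, 1)")
        if abs(sum(self.action_probs) - 1.0) > 1e-9:
            raise ValueError("action_probs must sum to 1")


@dataclass(frozen=True)
class FinetuneConfig:
    initial_lr: float = 1e-5
    decay_factor: float = 0.95
    decay_every: int = 100
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 10
    # optional early stop once validation accuracy reaches this level
    early_stop_val_acc: float | None = None
    # how often to run validation, in optimizer iterations; None = once per epoch.
    # Desk-scale models can cross from chance to ceiling inside a single epoch,
    # so epoch-level checkpoint selection is too coarse for them.
    val_every_batches: int | None = None

    def __post_init__(self):
        if not 0.0 < self.decay_factor <= 1.0:
            raise ValueError("decay_factor must lie in (0, 1]")


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict            # class label -> precision
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    absent_classes: list = field(default_factory=list)


@dataclass
class MLMTargets:
    """Selected corruption sites: parallel position / original-id arrays."""

    positions: np.ndarray
    original_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


def mlm_corrupt(seq: TokenSequence, cfg: PretrainConfig,
                rng: np.random.Generator,
                vocab: Vocabulary | None = None) -> tuple[TokenSequence, MLMTargets]:
    """Corrupt a token sequence for masked-LM training.

    Raises :class:`SkipRecord` when the sequence has no eligible position
    (everything is PAD or was an unknown residue in the raw input).
    """
    vocab = vocab or Vocabulary.default()
    eligible = np.flatnonzero(seq.mask & (seq.ids != vocab.mask_id))
    if eligible.size == 0:
        raise SkipRecord("no eligible positions for masked-LM corruption")
    n_targets = max(1, int(cfg.mask_fraction * eligible.size))
    positions = rng.choice(eligible, size=n_targets, replace=False)
    positions.sort()
    original = seq.ids[positions].copy()
    new_ids = seq.ids.copy()
    p_mask, p_rand, _ = cfg.action_probs
    u = rng.random(n_targets)
    mask_sel = u < p_mask
    rand_sel = (~mask_sel) & (u < p_mask + p_rand)
    new_ids[positions[mask_sel]] = vocab.mask_id
    if rand_sel.any():
        new_ids[positions[rand_sel]] = rng.integers(0, vocab.n_residues,
                                                    size=int(rand_sel.sum()))
    corrupted = TokenSequence(ids=new_ids, mask=seq.mask.copy(),
                              raw_length=seq.raw_length)
    return corrupted, MLMTargets(positions=positions, original_ids=original)


def mlm_loss(F_global, targets: MLMTargets, decoder) -> Tensor:
    """Mean cross-entropy of the position-wise decoder at the target sites."""
    if len(targets) == 0:
        raise ValueError("mlm_loss requires at least one target position")
    t = F_global if isinstance(F_global, Tensor) else Tensor(F_global)
    from .autograd import take_rows
    feats = take_rows(t, np.asarray(targets.positions))
    logits = decoder(feats)
    return _cross_entropy_from_logits(logits, targets.original_ids)


def _cross_entropy_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    lp = log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(lp * Tensor(onehot)).sum() * (1.0 / len(labels))


def pretrain_lr(step: int, cfg: PretrainConfig) -> float:
    return optim.pretrain_lr(step, cfg.peak_lr, cfg.warmup_steps)


def finetune_lr(iteration: int, cfg: FinetuneConfig) -> float:
    return optim.finetune_lr(iteration, cfg.initial_lr, cfg.decay_factor,
                             cfg.decay_every)


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _corrupt_batch(ids: np.ndarray, mask: np.ndarray, cfg: PretrainConfig,
                   rng: np.random.Generator, vocab: Vocabulary):
    """Vectorize corruption over a batch; returns flat target indexing arrays."""
    new_ids = ids.copy()
    seq_idx, positions, originals = [], [], []
    for b in range(ids.shape[0]):
        seq = TokenSequence(ids=ids[b], mask=mask[b], raw_length=int(mask[b].sum()))
        try:
            corrupted, tgt = mlm_corrupt(seq, cfg, rng, vocab)
        except SkipRecord:
            continue
        new_ids[b] = corrupted.ids
        seq_idx.append(np.full(len(tgt), b))
        positions.append(tgt.positions)
        originals.append(tgt.original_ids)
    if not positions:
        raise SkipRecord("batch contains no eligible record")
    return (new_ids,
            np.concatenate(seq_idx), np.concatenate(positions),
            np.concatenate(originals))


def _heldout_mlm_loss(model: DAttProtModel, ids: np.ndarray, mask: np.ndarray,
                      cfg: PretrainConfig, rng: np.random.Generator) -> float:
    model.eval()
    losses, weights = [], []
    with no_grad():
        for sel in _batches(len(ids), cfg.batch_size, None):
            try:
                new_ids, sidx, pos, orig = _corrupt_batch(
                    ids[sel], mask[sel], cfg, rng, model.vocab)
            except SkipRecord:
                continue
            logits = model.mlm_logits(new_ids, mask[sel], pos, sidx)
            loss = _cross_entropy_from_logits(logits, orig)
            losses.append(float(loss.data))
            weights.append(len(orig))
    model.train()
    return float(np.average(losses, weights=weights))


def pretrain(model: DAttProtModel, train_ids: np.ndarray, train_mask: np.ndarray,
             cfg: PretrainConfig, rng: np.random.Generator,
             val_ids: np.ndarray | None = None,
             val_mask: np.ndarray | None = None,
             log=None) -> dict:
    """Masked-LM pre-training loop; retains the best-validation-loss weights."""
    opt = optim.AdamW(model.parameters(), lr=0.0, weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "val_loss": []}
    best = (math.inf, model.state_dict())
    step = 0
    model.train()
    for epoch in range(cfg.max_epochs):
        epoch_losses, epoch_weights = [], []
        for sel in _batches(len(train_ids), cfg.batch_size, rng):
            try:
                new_ids, sidx, pos, orig = _corrupt_batch(
                    train_ids[sel], train_mask[sel], cfg, rng, model.vocab)
            except SkipRecord:
                continue
            logits = model.mlm_logits(new_ids, train_mask[sel], pos, sidx)
            loss = _cross_entropy_from_logits(logits, orig)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite masked-LM loss at step {step}")
            model.zero_grad()
            loss.backward()
            step += 1
            opt.lr = pretrain_lr(step, cfg)
            opt.step()
            epoch_losses.append(float(loss.data))
            epoch_weights.append(len(orig))
        train_loss = float(np.average(epoch_losses, weights=epoch_weights))
        history["train_loss"].append(train_loss)
        if val_ids is not None and len(val_ids):
            val_loss = _heldout_mlm_loss(model, val_ids, val_mask, cfg,
                                         np.random.default_rng(rng.integers(2**31)))
            history["val_loss"].append(val_loss)
            if val_loss < best[0]:
                best = (val_loss, model.state_dict())
        if log:
            log(f"pretrain epoch {epoch}: train={train_loss:.4f}"
                + (f" val={history['val_loss'][-1]:.4f}" if history["val_loss"] else ""))
    if history["val_loss"]:
        model.load_state_dict(best[1])
    return history


def finetune(model: DAttProtModel, train_ids: np.ndarray, train_mask: np.ndarray,
             train_y: np.ndarray, cfg: FinetuneConfig, rng: np.random.Generator,
             val_ids: np.ndarray | None = None,
             val_mask: np.ndarray | None = None,
             val_y: np.ndarray | None = None,
             log=None) -> dict:
    """Supervised fine-tuning on sequence labels; best-val-accuracy weights kept.

    The loss is the sequence-level cross-entropy of the aggregated class
    distribution p (not a per-position loss).
    """
    opt = optim.AdamW(model.parameters(), lr=cfg.initial_lr,
                      weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "val_accuracy": []}
    best = (-math.inf, model.state_dict())
    iteration = 0
    have_val = val_ids is not None and len(val_ids)
    stop = False

    def validate():
        nonlocal best, stop
        pred = predict_classes(model, val_ids, val_mask, cfg.batch_size)
        acc = float(np.mean(pred == val_y))
        history["val_accuracy"].append(acc)
        if acc > best[0]:
            best = (acc, model.state_dict())
        if (cfg.early_stop_val_acc is not None
                and acc >= cfg.early_stop_val_acc):
            stop = True
        model.train()
        return acc

    model.train()
    for epoch in range(cfg.max_epochs):
        epoch_losses = []
        for sel in _batches(len(train_ids), cfg.batch_size, rng):
            out = model.forward(train_ids[sel], train_mask[sel])
            logp = (out["p"] + 1e-12).log()
            onehot = np.zeros(logp.shape)
            onehot[np.arange(len(sel)), train_y[sel]] = 1.0
            loss = -(logp * Tensor(onehot)).sum() * (1.0 / len(sel))
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at iteration {iteration}")
            model.zero_grad()
            loss.backward()
            opt.lr = finetune_lr(iteration, cfg)
            opt.step()
            iteration += 1
            epoch_losses.append(float(loss.data))
            if (have_val and cfg.val_every_batches
                    and iteration % cfg.val_every_batches == 0):
                validate()
                if stop:
                    break
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if have_val and not stop and not cfg.val_every_batches:
            validate()
        if log:
            log(f"finetune epoch {epoch}: loss={history['train_loss'][-1]:.4f}"
                + (f" val_acc={history['val_accuracy'][-1]:.4f}"
                   if history["val_accuracy"] else ""))
        if stop:
            break
    if history["val_accuracy"]:
        model.load_state_dict(best[1])
    return history


def train(model: DAttProtModel, data: dict, cfg, rng: np.random.Generator,
          log=None) -> dict:
    """Dispatch to :func:`pretrain` or :func:`finetune` based on the config type."""
    if isinstance(cfg, PretrainConfig):
        return pretrain(model, data["ids"], data["mask"], cfg, rng,
                        data.get("val_ids"), data.get("val_mask"), log=log)
    if isinstance(cfg, FinetuneConfig):
        return finetune(model, data["ids"], data["mask"], data["y"], cfg, rng,
                        data.get("val_ids"), data.get("val_mask"),
                        data.get("val_y"), log=log)
    raise TypeError(f"unsupported config type: {type(cfg).__name__}")


def predict_proba_batched(model: DAttProtModel, ids: np.ndarray,
                          mask: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for sel in _batches(len(ids), batch_size, None):
        out.append(model.predict_proba(ids[sel], mask[sel]))
    return np.concatenate(out, axis=0)


def predict_classes(model: DAttProtModel, ids: np.ndarray, mask: np.ndarray,
                    batch_size: int = 64) -> np.ndarray:
    return predict_proba_batched(model, ids, mask, batch_size).argmax(axis=1)


def evaluate(predictions, labels) -> MetricsReport:
    """Accuracy plus one-vs-rest per-class P/R/F1 and unweighted macro averages."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    classes = np.unique(np.concatenate([labels, predictions]))
    p, r, f1, _ = precision_recall_fscore_support(
        labels, predictions, labels=classes, zero_division=0)
    absent = [c for c in classes if (labels != c).all() and (predictions != c).all()]
    return MetricsReport(
        accuracy=float(accuracy_score(labels, predictions)),
        precision={c: float(x) for c, x in zip(classes, p)},
        recall={c: float(x) for c, x in zip(classes, r)},
        f1={c: float(x) for c, x in zip(classes, f1)},
        macro_precision=float(p.mean()),
        macro_recall=float(r.mean()),
        macro_f1=float(f1.mean()),
        absent_classes=absent,
    )
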