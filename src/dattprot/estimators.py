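"""Scikit-learn style estimators wrapping the double-scale attention model.

:class:`MaskedLMPretrainer` fits the self-supervised trunk (embedding +
transformer encoders) on unlabeled sequences; :class:`DAttProtClassifier`
fine-tunes the full architecture on labeled sequences, optionally starting
from a pre-trained trunk.  Both take raw amino-acid strings as ``X`` and
follow the estimator contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``clone``-compatible constructors), so
they compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.preprocessing import LabelEncoder

from .doublescale_core import DoubleScaleAttention, ScaleSet
from .interpretability import (MotifAnnotation, MotifMatch, match_annotation,
                               match_rate, rank_and_select)
from .model import DAttProtModel, ModelConfig
from .sequence_codec import Vocabulary, normalize_sequence, regularize_length
from .training import (FinetuneConfig, PretrainConfig, finetune, pretrain,
                       predict_proba_batched)


def encode_sequences(X, l: int, rng: np.random.Generator, mode: str = "eval",
                     vocab: Vocabulary | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Normalize and length-regularize raw strings -> (ids, mask) arrays."""
    vocab = vocab or Vocabulary.default()
    ids = np.empty((len(X), l), dtype=np.int64)
    mask = np.empty((len(X), l), dtype=bool)
    for i, raw in enumerate(X):
        tokens = normalize_sequence(str(raw), rng)
        seq = regularize_length(tokens, l, mode=mode, rng=rng, vocab=vocab)
        ids[i] = seq.ids
        mask[i] = seq.mask
    return ids, mask


def _check_X(X):
    if isinstance(X, str):
        raise ValueError("X must be a sequence of strings, not a single string")
    X = list(X)
    if not X:
        raise ValueError("X is empty")
    return X


class MaskedLMPretrainer(TransformerMixin, BaseEstimator):
    """Self-supervised masked-LM pre-training of the encoder trunk.

    ``fit(X)`` trains on raw sequences; ``trunk_state_`` then holds the
    transferable embedding + encoder weights and ``transform(X)`` returns the
    per-position global features.
    """

    def __init__(self, l=128, f=64, n_layers=2, h=2, dropout=0.1, emb_dim=None,
                 mask_fraction=0.15, max_epochs=3, batch_size=32,
                 peak_lr=5e-5, warmup_steps=50_000, weight_decay=1e-4,
                 validation_fraction=0.05, random_state=0):
        self.l = l
        self.f = f
        self.n_layers = n_layers
        self.h = h
        self.dropout = dropout
        self.emb_dim = emb_dim
        self.mask_fraction = mask_fraction
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.peak_lr = peak_lr
        self.warmup_steps = warmup_steps
        self.weight_decay = weight_decay
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self) -> PretrainConfig:
        return PretrainConfig(mask_fraction=self.mask_fraction,
                              warmup_steps=self.warmup_steps,
                              peak_lr=self.peak_lr, max_epochs=self.max_epochs,
                              batch_size=self.batch_size,
                              weight_decay=self.weight_decay)

    def fit(self, X, y=None, log=None):
        X = _check_X(X)
        rng = np.random.default_rng(self.random_state)
        cfg = ModelConfig(l=self.l, f=self.f, emb_dim=self.emb_dim,
                          n_layers=self.n_layers, h=self.h, dropout=self.dropout)
        self.model_ = DAttProtModel(cfg, rng)
        ids, mask = encode_sequences(X, self.l, rng, mode="train")
        n_val = int(round(self.validation_fraction * len(X)))
        perm = rng.permutation(len(X))
        val, tr = perm[:n_val], perm[n_val:]
        self.history_ = pretrain(
            self.model_, ids[tr], mask[tr], self._config(), rng,
            val_ids=ids[val] if n_val else None,
            val_mask=mask[val] if n_val else None, log=log)
        self.trunk_state_ = self.model_.trunk_state_dict()
        return self

    def heldout_loss(self, X) -> float:
        """Masked-token cross-entropy on fresh data (natural-log units)."""
        from .training import _corrupt_batch, _heldout_mlm_loss
        X = _check_X(X)
        rng = np.random.default_rng(self.random_state + 1)
        ids, mask = encode_sequences(X, self.l, rng, mode="eval")
        return _heldout_mlm_loss(self.model_, ids, mask, self._config(), rng)

    def transform(self, X) -> np.ndarray:
        """Per-position global features F_global, shape (n, l, f)."""
        from .autograd import no_grad
        X = _check_X(X)
        rng = np.random.default_rng(self.random_state + 2)
        ids, mask = encode_sequences(X, self.l, rng, mode="eval")
        self.model_.eval()
        outs = []
        with no_grad():
            for i in range(0, len(ids), self.batch_size):
                outs.append(self.model_.encode(ids[i:i + self.batch_size],
                                               mask[i:i + self.batch_size]).data)
        return np.concatenate(outs, axis=0)


class DAttProtClassifier(ClassifierMixin, BaseEstimator):
    """Double-scale attention sequence classifier.

    Accepts raw amino-acid strings; exposes ``predict`` / ``predict_proba``
    plus the interpretability surface (:meth:`attention`, :meth:`explain`).
    ``pretrained_trunk`` may be a path or state dict produced by
    :class:`MaskedLMPretrainer`.
    """

    def __init__(self, l=128, f=64, n_layers=2, h=2, dropout=0.1, emb_dim=None,
                 kernel_sizes=(5, 10, 20), channel_mult=16, subspace_dim=None,
                 agreement_divisor="sqrt", include_global=True,
                 max_epochs=10, batch_size=32, initial_lr=1e-5,
                 decay_factor=0.95, decay_every=100, weight_decay=1e-4,
                 early_stop_val_acc=None, val_every_batches=None,
                 pretrained_trunk=None, random_state=0):
        self.l = l
        self.f = f
        self.n_layers = n_layers
        self.h = h
        self.dropout = dropout
        self.emb_dim = emb_dim
        self.kernel_sizes = kernel_sizes
        self.channel_mult = channel_mult
        self.subspace_dim = subspace_dim
        self.agreement_divisor = agreement_divisor
        self.include_global = include_global
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.decay_factor = decay_factor
        self.decay_every = decay_every
        self.weight_decay = weight_decay
        self.early_stop_val_acc = early_stop_val_acc
        self.val_every_batches = val_every_batches
        self.pretrained_trunk = pretrained_trunk
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None, log=None):
        X = _check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self._le = LabelEncoder().fit(y)
        self.classes_ = self._le.classes_
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        cfg = ModelConfig(l=self.l, f=self.f, emb_dim=self.emb_dim,
                          n_layers=self.n_layers, h=self.h, dropout=self.dropout,
                          kernel_sizes=tuple(self.kernel_sizes),
                          channel_mult=self.channel_mult,
                          subspace_dim=self.subspace_dim,
                          n_classes=len(self.classes_),
                          agreement_divisor=self.agreement_divisor,
                          include_global=self.include_global)
        self.model_ = DAttProtModel(cfg, rng)
        if self.pretrained_trunk is not None:
            self.model_.load_trunk(self.pretrained_trunk)
        ids, mask = encode_sequences(X, self.l, rng, mode="train")
        kw = {}
        if X_val is not None:
            vids, vmask = encode_sequences(_check_X(X_val), self.l, rng, "eval")
            kw = dict(val_ids=vids, val_mask=vmask,
                      val_y=self._le.transform(np.asarray(y_val)))
        ft = FinetuneConfig(initial_lr=self.initial_lr,
                            decay_factor=self.decay_factor,
                            decay_every=self.decay_every,
                            weight_decay=self.weight_decay,
                            batch_size=self.batch_size,
                            max_epochs=self.max_epochs,
                            early_stop_val_acc=self.early_stop_val_acc,
                            val_every_batches=self.val_every_batches)
        self.history_ = finetune(self.model_, ids, mask,
                                 self._le.transform(y), ft, rng, log=log, **kw)
        return self

    # ---- inference -----------------------------------------------------------
    def _encode_eval(self, X):
        rng = np.random.default_rng(self.random_state + 1)
        return encode_sequences(_check_X(X), self.l, rng, mode="eval")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        ids, mask = self._encode_eval(X)
        return predict_proba_batched(self.model_, ids, mask, self.batch_size)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self._le.inverse_transform(proba.argmax(axis=1))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # ---- interpretability ----------------------------------------------------
    def attention(self, X) -> list[DoubleScaleAttention]:
        """Per-sequence double-scale attention matrices (eval-mode windows)."""
        self._check_fitted()
        ids, mask = self._encode_eval(X)
        atts = []
        for i in range(0, len(ids), self.batch_size):
            atts.extend(self.model_.attention(ids[i:i + self.batch_size],
                                              mask[i:i + self.batch_size]))
        return atts

    def explain(self, X, annotations: list[list[MotifAnnotation]],
                scale_choice: str = "local") -> list[list[MotifMatch]]:
        """Match each sequence's annotations against its attention matrix and
        return the ranked (top-16) matches per sequence."""
        X = _check_X(X)
        atts = self.attention(X)
        scales = ScaleSet(tuple(self.kernel_sizes))
        out = []
        for raw, att, anns in zip(X, atts, annotations):
            vlen = min(len(raw), self.l)
            found = [m for m in (match_annotation(att, scales, a, valid_length=vlen,
                                                  scale_choice=scale_choice)
                                 for a in anns)
                     if isinstance(m, MotifMatch)]
            out.append(rank_and_select(found))
        return out

    def match_rate(self, X, annotations: list[list[MotifAnnotation]],
                   rng: np.random.Generator | None = None,
                   n_permutations: int = 20,
                   scale_choice: str = "local") -> tuple[float, float]:
        """Observed motif match rate vs. its length-preserving permutation
        baseline over the given annotated sequences."""
        X = _check_X(X)
        rng = rng or np.random.default_rng(self.random_state + 7)
        atts = self.attention(X)
        vlens = [min(len(s), self.l) for s in X]
        return match_rate(atts, ScaleSet(tuple(self.kernel_sizes)), annotations,
                          rng, n_permutations=n_permutations,
                          valid_lengths=vlens, scale_choice=scale_choice)
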