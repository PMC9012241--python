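"""The full double-scale attention classifier (DAttProt architecture).

Stages: token embedding (scaled, plus sinusoidal positional encoding) ->
transformer encoder stack -> multi-scale convolutions -> feature agreement ->
double-scale attention matrix -> position-wise mixture -> position-wise
linear classifier -> aggregation under the positional margin.

The same embedding + encoder trunk serves the masked-LM pre-training head, so
pre-trained trunk weights transfer into fine-tuning via
:meth:`DAttProtModel.save_trunk` / :meth:`load_trunk`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, log_softmax, no_grad, take_rows
from .classifier_head import PositionwiseClassifier, PredictionBundle, aggregate
from .doublescale_core import (DoubleScaleAttention, MultiScaleExtractor, ScaleSet,
                               agreement_scores, attention_matrix, central_vectors,
                               mix_features)
from .nn import Embedding, Linear, Module
from .sequence_codec import TokenSequence, Vocabulary, embed, positional_encoding
from .transformer_encoder import EncoderConfig, TransformerEncoder


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the whole model.

    ``emb_dim`` is the width of the raw token embedding; when it differs from
    the hidden dimension ``f`` (the full-scale setting uses 16 -> 512) a
    learned linear projection bridges the two before the positional encoding
    is added at width f.  ``subspace_dim`` is the agreement subspace; None
    means f.  Defaults are the desk-scale configuration.
    """

    l: int = 128
    f: int = 64
    emb_dim: int | None = None
    n_layers: int = 2
    h: int = 2
    dropout: float = 0.1
    kernel_sizes: tuple[int, ...] = (5, 10, 20)
    channel_mult: int = 16
    subspace_dim: int | None = None
    n_classes: int = 2
    agreement_divisor: str = "sqrt"
    include_global: bool = True

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(n_layers=self.n_layers, h=self.h, f=self.f,
                             dropout=self.dropout)


class DAttProtModel(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None,
                 vocab: Vocabulary | None = None):
        super().__init__()
        self.cfg = cfg
        self.vocab = vocab or Vocabulary.default()
        rng = rng or np.random.default_rng(0)
        emb_dim = cfg.emb_dim if cfg.emb_dim is not None else cfg.f
        self.embedding = Embedding(self.vocab.size, emb_dim, rng,
                                   pad_id=self.vocab.pad_id)
        self.emb_proj = Linear(emb_dim, cfg.f, rng) if emb_dim != cfg.f else None
        self.encoder = TransformerEncoder(cfg.encoder_config(), rng)
        self.scales = ScaleSet(cfg.kernel_sizes)
        self.extractor = MultiScaleExtractor(cfg.f, self.scales, rng,
                                             channel_mult=cfg.channel_mult,
                                             subspace_dim=cfg.subspace_dim)
        # agreement happens in the extractor's subspace; when it differs from f
        # the global features need a learned projection to join the central mean
        sub = self.extractor.subspace_dim
        self.global_proj = Linear(cfg.f, sub, rng) if sub != cfg.f else None
        self.head = PositionwiseClassifier(
            cfg.subspace_dim if cfg.subspace_dim is not None else cfg.f,
            cfg.n_classes, rng)
        self.mlm_decoder = Linear(cfg.f, self.vocab.n_residues, rng)
        self._pe = positional_encoding(cfg.l, cfg.f)

    # ---- trunk ---------------------------------------------------------------
    def encode(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """ids/mask (B, l) -> F_global (B, l, f)."""
        seq = TokenSequence(ids=ids, mask=mask, raw_length=int(mask.sum(axis=-1).max()))
        pe = self._pe if ids.shape[-1] == self.cfg.l \
            else positional_encoding(ids.shape[-1], self.cfg.f)
        S = embed(seq, self.embedding.table, self.cfg.f,
                  projection=self.emb_proj, pe=pe)
        return self.encoder(S, mask)

    # ---- classification path -------------------------------------------------
    def forward(self, ids: np.ndarray, mask: np.ndarray) -> dict[str, Tensor]:
        """Full classification pass; returns all intermediate tensors."""
        F_global = self.encode(ids, mask)
        maps = self.extractor(F_global, mask)
        g = self.global_proj(F_global) if self.global_proj is not None else F_global
        centers = central_vectors(g, maps,
                                  include_global=self.cfg.include_global)
        A = agreement_scores(maps, centers, divisor=self.cfg.agreement_divisor)
        W, v = attention_matrix(A, mask)
        F_mixed = mix_features(W, v, maps, mask)
        C = self.head(F_mixed)
        p = aggregate(C, v)
        return {"F_global": F_global, "maps": maps, "A": A, "W": W, "v": v,
                "F_mixed": F_mixed, "C": C, "p": p}

    def predict_proba(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        self.eval()
        with no_grad():
            return self.forward(ids, mask)["p"].data

    def predict_bundle(self, ids: np.ndarray, mask: np.ndarray) -> list[PredictionBundle]:
        self.eval()
        with no_grad():
            out = self.forward(ids, mask)
        return [PredictionBundle(C=c, p=p) for c, p in zip(out["C"].data, out["p"].data)]

    def attention(self, ids: np.ndarray, mask: np.ndarray) -> list[DoubleScaleAttention]:
        """Per-sequence double-scale attention matrices (the interpretability output)."""
        self.eval()
        with no_grad():
            out = self.forward(ids, mask)
        return [DoubleScaleAttention(W=w, v=v, kernel_sizes=self.scales.kernel_sizes)
                for w, v in zip(out["W"].data, out["v"].data)]

    # ---- masked-LM path ------------------------------------------------------
    def mlm_logits(self, ids: np.ndarray, mask: np.ndarray,
                   positions: np.ndarray, seq_index: np.ndarray) -> Tensor:
        """Decoder logits over residue tokens at the given (sequence, position)
        targets.  ``positions``/``seq_index`` are flat parallel arrays."""
        F_global = self.encode(ids, mask)
        B, l, f = F_global.shape
        flat = F_global.reshape(B * l, f)
        gathered = take_rows(flat, seq_index * l + positions)
        return self.mlm_decoder(gathered)

    # ---- weight transfer -----------------------------------------------------
    _TRUNK_PREFIXES = ("embedding.", "emb_proj.", "encoder.")

    def trunk_state_dict(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.state_dict().items()
                if k.startswith(self._TRUNK_PREFIXES)}

    def save_trunk(self, path) -> None:
        np.savez(path, **self.trunk_state_dict())

    def load_trunk(self, source) -> None:
        """Load pre-trained embedding + encoder weights from a path or dict."""
        if isinstance(source, dict):
            state = source
        else:
            with np.load(source) as npz:
                state = {k: npz[k] for k in npz.files}
        own = dict(self.named_parameters())
        trunk_keys = {k for k in own if k.startswith(self._TRUNK_PREFIXES)}
        if set(state) != trunk_keys:
            raise KeyError("checkpoint does not match this model's trunk: "
                           f"missing={sorted(trunk_keys - set(state))}, "
                           f"unexpected={sorted(set(state) - trunk_keys)}")
        for k in trunk_keys:
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != own[k].data.shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k].data = arr.copy()
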