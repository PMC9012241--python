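"""Transformer encoder stack producing per-position global features.

Each layer is a post-norm encoder block (multi-head scaled dot-product
self-attention and a position-wise feed-forward network, both wrapped in
residual connections with layer normalization).  Attention logits toward PAD
positions are forced to -inf so padding never participates, and PAD output
rows are kept at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .nn import EncoderLayer, Module, MultiHeadSelfAttention


@dataclass(frozen=True)
class EncoderConfig:
    """Hyper-parameters of the encoder stack.

    The per-head key/value dimensions are tied: d_k = d_v = f / h.  The
    full-scale model uses h=8, f=512 (so d_k = 64) with 3 or 6 layers; the
    desk-scale default is far smaller.
    """

    n_layers: int = 2
    h: int = 2
    f: int = 64
    d_ff: int | None = None
    dropout: float = 0.1

    def __post_init__(self):
        if self.f % self.h != 0:
            raise ValueError(f"f={self.f} must be divisible by h={self.h}")
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1): {self.dropout}")

    @property
    def d_k(self) -> int:
        return self.f // self.h

    d_v = d_k

    @property
    def inner_dim(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.f


class TransformerEncoder(Module):
    """Stack of encoder layers; output is the layer-normalized global feature map."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.layers = [EncoderLayer(cfg.f, cfg.h, cfg.inner_dim, rng, cfg.dropout)
                       for _ in range(cfg.n_layers)]

    def __call__(self, S: Tensor, mask: np.ndarray) -> Tensor:
        x = S
        for layer in self.layers:
            x = layer(x, mask)
        return x


# ---- functional surface (single sequence, ndarray in / ndarray out) -----------
def _as_batch(F_in: np.ndarray | Tensor) -> tuple[Tensor, bool]:
    t = F_in if isinstance(F_in, Tensor) else Tensor(F_in)
    if t.ndim == 2:
        return t.reshape(1, *t.shape), True
    return t, False


def multi_head_self_attention(F_in, mask: np.ndarray,
                              params: MultiHeadSelfAttention) -> np.ndarray:
    """Apply one multi-head self-attention module to an l x f feature matrix."""
    t, squeeze = _as_batch(F_in)
    m = np.atleast_2d(np.asarray(mask, dtype=bool))
    out = params(t, m)
    return out.data[0] if squeeze else out.data


def encoder_layer(F_in, mask: np.ndarray, params: EncoderLayer) -> np.ndarray:
    """Apply one full encoder layer (attention + FFN, residuals + layer norm)."""
    t, squeeze = _as_batch(F_in)
    m = np.atleast_2d(np.asarray(mask, dtype=bool))
    out = params(t, m)
    return out.data[0] if squeeze else out.data


def encode(S, mask: np.ndarray, stack: TransformerEncoder) -> np.ndarray:
    """Run the embedded sequence through the whole stack -> F_global (l x f)."""
    t, squeeze = _as_batch(S)
    m = np.atleast_2d(np.asarray(mask, dtype=bool))
    out = stack(t, m)
    return out.data[0] if squeeze else out.data
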