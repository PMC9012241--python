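"""Neural-network building blocks on top of :mod:`dattprot.autograd`.

Layers follow the familiar Module pattern: parameters are discovered by
attribute walking, ``train()``/``eval()`` toggle dropout, and ``state_dict`` /
``load_state_dict`` move weights in and out as plain ndarrays (saved with
``numpy.savez`` so encoder weights pre-trained on the masked-LM task can be
transferred into a fine-tuning model).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, concat, gelu, softmax, take_rows


class Parameter(Tensor):
    """A Tensor that is updated by optimizers."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, mode switching, weight (de)serialization."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...] | None = None) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.W = Parameter(_xavier(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 pad_id: int | None = None):
        super().__init__()
        table = rng.normal(0.0, 0.02, size=(n_tokens, dim))
        if pad_id is not None:
            table[pad_id] = 0.0  # PAD embeds to zero and receives no gradient
        self.table = Parameter(table)
        self.pad_id = pad_id

    def __call__(self, ids: np.ndarray) -> Tensor:
        return take_rows(self.table, np.asarray(ids))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


def attention_mask_bias(mask: np.ndarray) -> np.ndarray:
    """(B, l) boolean validity mask -> (B, 1, 1, l) additive bias, -inf at PAD."""
    bias = np.where(mask, 0.0, -np.inf)
    return bias[:, None, None, :]


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with h heads; PAD keys masked to -inf."""

    def __init__(self, f: int, h: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        if f % h != 0:
            raise ValueError(f"feature dimension {f} not divisible by {h} heads")
        self.f, self.h, self.d_k = f, h, f // h
        self.W_Q = Linear(f, f, rng)
        self.W_K = Linear(f, f, rng)
        self.W_V = Linear(f, f, rng)
        self.W_O = Linear(f, f, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, l, f = x.shape
        if not mask.any(axis=-1).all():
            raise ValueError("degenerate input: a sequence is entirely PAD")

        def split(t: Tensor) -> Tensor:  # (B, l, f) -> (B, h, l, d_k)
            return t.reshape(B, l, self.h, self.d_k).transpose(0, 2, 1, 3)

        Q, K, V = split(self.W_Q(x)), split(self.W_K(x)), split(self.W_V(x))
        logits = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        logits = logits + Tensor(attention_mask_bias(mask))
        attn = softmax(logits, axis=-1)
        attn = self.drop(attn)
        out = (attn @ V).transpose(0, 2, 1, 3).reshape(B, l, f)
        return self.W_O(out)


class FeedForward(Module):
    """Position-wise two-layer MLP with GELU, inner dimension d_ff."""

    def __init__(self, f: int, d_ff: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.lin1 = Linear(f, d_ff, rng)
        self.lin2 = Linear(d_ff, f, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.drop(gelu(self.lin1(x))))


class EncoderLayer(Module):
    """Post-norm transformer encoder layer: LN(x + Attn(x)), LN(x + FF(x))."""

    def __init__(self, f: int, h: int, d_ff: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.attn = MultiHeadSelfAttention(f, h, rng, dropout)
        self.norm1 = LayerNorm(f)
        self.ff = FeedForward(f, d_ff, rng, dropout)
        self.norm2 = LayerNorm(f)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, mask)))
        x = self.norm2(x + self.drop(self.ff(x)))
        # keep PAD rows exactly zero so they stay inert downstream
        return x * Tensor(mask[..., None].astype(np.float64))


class Conv1dSame(Module):
    """1-D convolution over positions, stride 1, output length = input length.

    Same-length padding uses the left-of-center window convention: output row j
    summarizes input rows j - ceil((S-1)/2) ... j + floor((S-1)/2), with zeros
    outside the sequence.  The raw convolution output is divided by sqrt(S) to
    counter variance growth with window size.
    """

    def __init__(self, f_in: int, channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size < 1:
            raise ValueError(f"kernel size must be >= 1: {kernel_size}")
        self.S = kernel_size
        self.f_in = f_in
        self.channels = channels
        self.W = Parameter(_xavier(rng, kernel_size * f_in, channels))
        self.b = Parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        B, l, f = x.shape
        if l < self.S:
            raise ValueError(f"kernel size {self.S} exceeds sequence length {l}")
        left = (self.S - 1 + 1) // 2   # ceil((S-1)/2)
        right = (self.S - 1) // 2      # floor((S-1)/2)
        pads = []
        if left:
            pads.append(Tensor(np.zeros((B, left, f))))
        pads.append(x)
        if right:
            pads.append(Tensor(np.zeros((B, right, f))))
        xp = concat(pads, axis=1) if len(pads) > 1 else x
        # gather windows: (l_pad, B, f) indexed by (l, S) -> (l, S, B, f)
        xt = xp.transpose(1, 0, 2)
        idx = np.arange(l)[:, None] + np.arange(self.S)[None, :]
        win = take_rows(xt, idx)                       # (l, S, B, f)
        win = win.transpose(2, 0, 1, 3).reshape(B, l, self.S * f)
        out = (win @ self.W + self.b) * (1.0 / np.sqrt(self.S))
        return out
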