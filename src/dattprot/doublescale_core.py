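"""Multi-scale convolutional features, feature agreement, and the
probabilistic double-scale attention matrix.

The pipeline: the encoder's global feature map F_global (l x f) is convolved
at N kernel sizes S_0 < ... < S_{N-1} (stride 1, same-length, left-of-center
windows), each raw output divided by sqrt(S_k) against variance growth, then
activated and linearly projected into a shared agreement subspace.  At every
position j the central vector averages F_global^j with all N scale vectors;
each scale's agreement score is its scaled dot product with that central
vector.  A single softmax over all N*l agreement scores yields the
double-scale attention matrix W — a joint probability distribution over
(spatial scale, position) — whose column sums form the positional margin v.
Conditional weights W_kj / v_j then mix the scale features position-wise into
F_mixed.

W and v are the interpretability objects: W_kj is the probability mass the
classifier's attention puts on "an S_k-sized pattern centered at position j".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, gelu, softmax
from .nn import Conv1dSame, Linear, Module

DEFAULT_KERNEL_SIZES = (5, 10, 20)


@dataclass(frozen=True)
class ScaleSet:
    """Ordered convolution kernel sizes (the spatial scales)."""

    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES

    def __post_init__(self):
        ks = tuple(int(k) for k in self.kernel_sizes)
        object.__setattr__(self, "kernel_sizes", ks)
        if not ks:
            raise ValueError("need at least one kernel size")
        if any(k < 1 for k in ks):
            raise ValueError(f"kernel sizes must be >= 1: {ks}")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError(f"kernel sizes must be strictly increasing: {ks}")

    def __len__(self) -> int:
        return len(self.kernel_sizes)

    def closest(self, length: int) -> int:
        """Kernel size closest to `length`; ties resolved to the smaller kernel."""
        return min(self.kernel_sizes, key=lambda k: (abs(k - length), k))


@dataclass
class DoubleScaleAttention:
    """Joint distribution W (N x l) over (scale, position) and its margin v (l,)."""

    W: np.ndarray
    v: np.ndarray
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.W.ndim != 2 or self.v.ndim != 1 or self.W.shape[1] != self.v.shape[0]:
            raise ValueError("W must be N x l and v length l")


class MultiScaleExtractor(Module):
    """Per-scale Conv1d (channels = channel_mult * S_k) -> GELU -> linear
    projection into the shared agreement subspace (default dimension f)."""

    def __init__(self, f: int, scales: ScaleSet, rng: np.random.Generator,
                 channel_mult: int = 16, subspace_dim: int | None = None):
        super().__init__()
        self.scales = scales
        self.subspace_dim = subspace_dim if subspace_dim is not None else f
        self.convs = [Conv1dSame(f, channel_mult * k, k, rng)
                      for k in scales.kernel_sizes]
        self.projs = [Linear(channel_mult * k, self.subspace_dim, rng)
                      for k in scales.kernel_sizes]

    def __call__(self, F_global: Tensor, mask: np.ndarray) -> list[Tensor]:
        valid = Tensor(np.asarray(mask, dtype=np.float64)[..., None])
        maps = []
        for conv, proj in zip(self.convs, self.projs):
            m = proj(gelu(conv(F_global)))
            maps.append(m * valid)  # zero PAD-centered rows
        return maps


def _stack_scales(maps: list[Tensor]) -> Tensor:
    """list of (B, l, f) -> (B, N, l, f)."""
    B, l, f = maps[0].shape
    return concat([m.reshape(B, 1, l, f) for m in maps], axis=1)


def central_vectors(F_global: Tensor, maps: list[Tensor],
                    include_global: bool = True) -> Tensor:
    """Position-wise mean of the global vector and all N scale vectors.

    ``include_global=False`` is the ablation that drops F_global's supervision
    from the average (mean over the N scale maps only).
    """
    if any(m.shape != F_global.shape for m in maps):
        raise ValueError("scale maps and F_global must share shape l x f")
    total = maps[0]
    for m in maps[1:]:
        total = total + m
    if include_global:
        return (total + F_global) * (1.0 / (len(maps) + 1))
    return total * (1.0 / len(maps))


def agreement_scores(maps: list[Tensor], centers: Tensor,
                     divisor: str = "sqrt") -> Tensor:
    """Scaled dot product of each scale vector with the central vector.

    ``divisor`` selects the normalization of the dot product: ``"sqrt"``
    (default) divides by sqrt(f) as in scaled dot-product attention; ``"dim"``
    divides by f.  Returns the agreement matrix A of shape (B, N, l).
    """
    f = centers.shape[-1]
    if divisor == "sqrt":
        scale = 1.0 / np.sqrt(f)
    elif divisor == "dim":
        scale = 1.0 / f
    else:
        raise ValueError(f"divisor must be 'sqrt' or 'dim': {divisor!r}")
    stacked = _stack_scales(maps)                    # (B, N, l, f)
    B, N, l, _ = stacked.shape
    c = centers.reshape(B, 1, l, f)
    A = (stacked * c).sum(axis=-1) * scale           # (B, N, l)
    if not np.isfinite(A.data).all():
        raise FloatingPointError("non-finite agreement scores")
    return A


def attention_matrix(A: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Joint softmax over all N*l agreement scores -> (W, v).

    PAD columns receive a -inf sentinel before the softmax, so their mass is
    exactly zero; W sums to 1 over all entries and v = column sums of W over
    the N scales sums to 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("degenerate input: all positions are PAD")
    B, N, l = A.shape
    bias = np.where(mask, 0.0, -np.inf)[:, None, :]   # (B, 1, l)
    logits = (A + Tensor(np.broadcast_to(bias, (B, N, l)).copy())).reshape(B, N * l)
    W = softmax(logits, axis=-1).reshape(B, N, l)
    v = W.sum(axis=1)                                 # (B, l)
    return W, v


def mix_features(W: Tensor, v: Tensor, maps: list[Tensor],
                 mask: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Position-wise convex mixture of scale features with weights W_kj / v_j.

    PAD rows are zero.  ``eps`` guards the division at positions whose margin
    underflows.
    """
    stacked = _stack_scales(maps)                     # (B, N, l, f)
    B, N, l, f = stacked.shape
    cond = W / (v.reshape(B, 1, l) + eps)             # (B, N, l)
    mixed = (cond.reshape(B, N, l, 1) * stacked).sum(axis=1)
    valid = Tensor(np.asarray(mask, dtype=np.float64)[..., None])
    return mixed * valid


def extract_scale_features(F_global, scales: ScaleSet,
                           params: MultiScaleExtractor,
                           mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Functional wrapper: run the multi-scale extractor on an l x f map."""
    t = F_global if isinstance(F_global, Tensor) else Tensor(F_global)
    squeeze = t.ndim == 2
    if squeeze:
        t = t.reshape(1, *t.shape)
    if mask is None:
        m = np.ones(t.shape[:2], dtype=bool)
    else:
        m = np.atleast_2d(np.asarray(mask, dtype=bool))
    if params.scales.kernel_sizes != scales.kernel_sizes:
        raise ValueError("extractor was built for different kernel sizes")
    maps = params(t, m)
    return [mp.data[0] if squeeze else mp.data for mp in maps]
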