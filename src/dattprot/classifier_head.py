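"""Position-wise linear classification and probabilistic aggregation.

A single full-connection layer maps each mixed feature vector to class
logits; a softmax per position yields the positional prediction matrix C
(l x M), row j being the class distribution conditioned on position j.  The
final class distribution is the expectation of those rows under the
positional attention margin v:  p_d = sum_j C_jd * v_j  (law of total
probability over positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, softmax
from .nn import Linear, Module


@dataclass
class PredictionBundle:
    """Positional class scores C (l x M) and aggregated distribution p (M,)."""

    C: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.C.ndim != 2 or self.p.ndim != 1 or self.C.shape[1] != self.p.shape[0]:
            raise ValueError("C must be l x M and p length M")

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.p))


class PositionwiseClassifier(Module):
    """One linear layer shared across positions, softmaxed per position."""

    def __init__(self, f: int, n_classes: int, rng: np.random.Generator):
        super().__init__()
        if n_classes < 2:
            raise ValueError(f"need at least 2 classes: {n_classes}")
        self.linear = Linear(f, n_classes, rng)
        self.n_classes = n_classes

    def __call__(self, F_mixed: Tensor) -> Tensor:
        return softmax(self.linear(F_mixed), axis=-1)


def positional_predictions(F_mixed, params: PositionwiseClassifier) -> np.ndarray:
    """Functional wrapper -> C with rows summing to one."""
    t = F_mixed if isinstance(F_mixed, Tensor) else Tensor(F_mixed)
    squeeze = t.ndim == 2
    if squeeze:
        t = t.reshape(1, *t.shape)
    out = params(t)
    return out.data[0] if squeeze else out.data


def aggregate(C, v, tol: float = 1e-4):
    """Expectation of positional predictions under the margin v.

    Works on Tensors (training path, gradients flow) and ndarrays alike.
    ``v`` must be normalized to 1 within ``tol``.
    """
    v_data = v.data if isinstance(v, Tensor) else np.asarray(v, dtype=np.float64)
    sums = v_data.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError(f"margin v is not normalized (sum={sums})")
    if isinstance(C, Tensor) or isinstance(v, Tensor):
        Ct = C if isinstance(C, Tensor) else Tensor(C)
        vt = v if isinstance(v, Tensor) else Tensor(v)
        # (..., l, M) weighted by (..., l) -> (..., M)
        return (Ct * vt.reshape(*v_data.shape, 1)).sum(axis=-2)
    C = np.asarray(C, dtype=np.float64)
    return np.einsum("...lm,...l->...m", C, v_data)
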