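"""AdamW optimizer and the learning-rate schedules used in training.

Pre-training uses a linear warm-up to a peak rate followed by inverse-
square-root decay; fine-tuning uses a stepwise exponential decay (multiply by
a fixed factor once per hundred iterations).
"""

from __future__ import annotations

import numpy as np

from .nn import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied directly to the weights (not through the
    gradient), scaled by the current learning rate, as in the decoupled
    formulation.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def pretrain_lr(step: int, peak_lr: float, warmup_steps: int) -> float:
    """Warm-up then inverse-sqrt decay; continuous at the warm-up boundary.

    Ramps linearly from 0 to ``peak_lr`` over ``warmup_steps`` updates, then
    decays as ``peak_lr * sqrt(warmup_steps / step)``.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if step <= warmup_steps:
        return peak_lr * step / max(warmup_steps, 1)
    return peak_lr * np.sqrt(warmup_steps / step)


def finetune_lr(iteration: int, initial_lr: float = 1e-5,
                decay_factor: float = 0.95, decay_every: int = 100) -> float:
    """Stepwise exponential decay: initial_lr * factor**(iteration // every)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return initial_lr * decay_factor ** (iteration // decay_every)
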