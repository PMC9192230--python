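"""Neural layers, optimizer and losses on top of the autodiff engine.

Modules own their parameters as :class:`~uatransnet.engine.Tensor` objects
and expose ``parameters()`` / ``state_dict()`` by attribute path, which is
what the EMA teacher update and checkpointing operate on.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import Tensor, conv2d, group_norm

DTYPE = np.float32


class Module:
    """Base class: recursive parameter discovery over attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match module parameters")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Same-padded stride-1 convolution with He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        fan_in = c_in * k * k
        scale = 0.0 if zero_init else math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(DTYPE),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias)


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by {groups} groups")
        self.groups = groups
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)

    def forward(self, x):
        return group_norm(x, self.gamma, self.beta, self.groups)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.weight = Tensor((rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def base_lr(epoch: int, lr_initial: float = 1e-3, lr_late: float = 1e-4,
            switch_epoch: int = 50) -> float:
    """Baseline learning rate of the schedule's current phase: `lr_initial`
    until `switch_epoch`, `lr_late` afterwards."""
    return lr_initial if epoch < switch_epoch else lr_late


def step_cosine_lr(epoch: int, total_epochs: int, lr_initial: float = 1e-3,
                   lr_late: float = 1e-4, switch_epoch: int = 50) -> float:
    """Cosine annealing over the full run applied to the phase baseline."""
    base = base_lr(epoch, lr_initial, lr_late, switch_epoch)
    return 0.5 * base * (1.0 + math.cos(math.pi * epoch / max(total_epochs, 1)))


EPS = 1e-7


def bce_loss(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on probabilities (natural log, eps-clipped)."""
    p = probs.clip(EPS, 1.0 - EPS)
    t = np.asarray(targets, dtype=p.data.dtype)
    return -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()).mean()


def dice_loss(probs: Tensor, targets: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss, 1 - 2|P∩T|/(|P|+|T|), smoothed for empty masks."""
    t = Tensor(np.asarray(targets, dtype=probs.data.dtype))
    inter = (probs * t).sum()
    denom = probs.sum() + t.sum()
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)
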