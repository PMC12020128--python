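"""Small neural-network building blocks on top of :mod:`cdpd.autodiff`.

Layers hold their parameters as named :class:`~cdpd.autodiff.Tensor`
leaves; :meth:`Module.named_parameters` walks submodules recursively so
optimizers and checkpoints see a flat ``name -> Tensor`` mapping.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "Conv2d", "Sequential", "SGD",
           "save_params", "load_params"]


class Module:
    """Base class: submodules and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}/")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}/")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(rng.normal(0.0, scale, (out_features, in_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose() + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 scale: float | None = None):
        k = int(kernel_size)
        if scale is None:
            scale = 1.0 / np.sqrt(in_channels * k * k)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels, k, k)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = int(stride)
        self.padding = int(padding)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class SGD:
    """Gradient descent with optional momentum over named parameter groups.

    ``groups`` maps a group name to ``(params, lr)``; learning rates can be
    changed between steps (schedules) and a group can be frozen by setting
    its rate to zero or removing it.  With ``momentum=0`` the update is the
    plain ``p -= lr * grad``.
    """

    def __init__(self, groups: dict[str, tuple[list[Tensor], float]],
                 momentum: float = 0.0, max_grad_norm: float | None = None):
        self.groups = {name: (list(ps), float(lr)) for name, (ps, lr) in groups.items()}
        self.momentum = float(momentum)
        self.max_grad_norm = max_grad_norm
        self._velocity: dict[int, np.ndarray] = {}

    def set_lr(self, name: str, lr: float):
        ps, _ = self.groups[name]
        self.groups[name] = (ps, float(lr))

    def zero_grad(self):
        for ps, _ in self.groups.values():
            for p in ps:
                p.grad = None

    def step(self) -> bool:
        """Apply one update; returns False (no-op) if any gradient is non-finite."""
        for ps, _ in self.groups.values():
            for p in ps:
                if p.grad is not None and not np.all(np.isfinite(p.grad)):
                    return False
        if self.max_grad_norm is not None:
            sq = sum(float((p.grad ** 2).sum())
                     for ps, _ in self.groups.values()
                     for p in ps if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / norm
                for ps, _ in self.groups.values():
                    for p in ps:
                        if p.grad is not None:
                            p.grad = p.grad * scale
        for ps, lr in self.groups.values():
            if lr == 0.0:
                continue
            for p in ps:
                if p.grad is None:
                    continue
                if self.momentum > 0.0:
                    v = self._velocity.get(id(p))
                    v = p.grad if v is None else self.momentum * v + p.grad
                    self._velocity[id(p)] = v
                else:
                    v = p.grad
                p.data = p.data - lr * v
        return True


def save_params(path, state: dict[str, np.ndarray], **scalars):
    """Single-file archive of named parameter arrays plus scalar config."""
    payload = {f"param::{k}": v for k, v in state.items()}
    for k, v in scalars.items():
        payload[f"scalar::{k}"] = np.asarray(v)
    np.savez(path, **payload)


def load_params(path) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    with np.load(path) as archive:
        state, scalars = {}, {}
        for key in archive.files:
            kind, name = key.split("::", 1)
            if kind == "param":
                state[name] = archive[key]
            else:
                scalars[name] = archive[key].item()
    return state, scalars
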