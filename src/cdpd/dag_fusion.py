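"""Dynamic Adaptive Gate (DAG): learnable gated cross-branch feature fusion.

At each fusion point, the source branch's feature map ``f_src`` (shape
``N x C x H x W``) produces

* a per-channel gate ``x = sigmoid(W . gap(f_src) + b)`` in ``(0,1)^C``,
  where ``gap`` is global average pooling over H and W (the "fully
  connected layer" acts on the channel descriptor, so parameter count is
  independent of spatial size), and
* a transform ``o = GeLU(U * f_src + e)`` computed by a 1x1 channel-mixing
  convolution, matching the source map's shape.

The fused destination feature is ``f_dst + x (x) o`` with the gate
broadcast over H x W.  When branch channel counts differ, a learnable 1x1
projection on the source side maps the message into the destination's
channel space (identity when counts match).  Both directions of a
bidirectional fusion are computed from the PRE-fusion features, so the
update is simultaneous and order-independent.

Zeroing ``U`` and ``e`` makes every fusion point an exact no-op
(``GeLU(0) = 0``), which is also how the identity-fusion equivalence is
tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Conv2d, Module

__all__ = ["GateParams", "FeatureMap", "gate_weight", "transform", "fuse",
           "bidirectional_fuse", "gate_message", "gate_suppression_experiment"]


@dataclass
class FeatureMap:
    """A branch feature map tagged with its branch and backbone stage."""

    values: Tensor
    branch: str = "main"        # {"main", "aux"}
    stage: int = 0


def _values(f) -> Tensor:
    return f.values if isinstance(f, FeatureMap) else f


class GateParams(Module):
    """Per-fusion-point, per-direction gate (W, b) and transform (U, e).

    ``src_channels``/``dst_channels`` are the channel counts of the source
    and destination feature maps.  The transform is initialized at a small
    scale ``init_scale`` (exactly zero gives an exact-identity fusion)."""

    def __init__(self, src_channels: int, dst_channels: int | None = None,
                 rng: np.random.Generator | None = None,
                 init_scale: float = 0.05):
        rng = rng if rng is not None else np.random.default_rng(0)
        dst_channels = src_channels if dst_channels is None else dst_channels
        self.src_channels = src_channels
        self.dst_channels = dst_channels
        # gate: channel descriptor -> per-channel gate logit
        self.W = Tensor(np.zeros((src_channels, src_channels)), requires_grad=True)
        self.b = Tensor(np.zeros(src_channels), requires_grad=True)
        # transform: 1x1 channel-mixing affine
        self.U = Tensor(rng.normal(0.0, init_scale,
                                   (src_channels, src_channels, 1, 1)),
                        requires_grad=True)
        self.e = Tensor(np.zeros(src_channels), requires_grad=True)
        if dst_channels != src_channels:
            self.proj = Conv2d(src_channels, dst_channels, 1, rng)
        else:
            self.proj = None

    def zero_transform(self):
        """Zero U and e so this fusion point becomes an exact no-op."""
        self.U.data = np.zeros_like(self.U.data)
        self.e.data = np.zeros_like(self.e.data)


def gate_weight(f_src, p: GateParams) -> Tensor:
    """Per-channel gate ``sigmoid(W . gap(f_src) + b)`` in ``(0,1)^C``,
    shape (N, C)."""
    f = _values(f_src)
    if f.shape[1] != p.src_channels:
        raise ValueError(f"feature has {f.shape[1]} channels, "
                         f"gate expects {p.src_channels}")
    descriptor = f.mean(axis=(2, 3))            # (N, C)
    return (descriptor @ p.W.transpose() + p.b).sigmoid()


def transform(f_src, p: GateParams) -> Tensor:
    """GeLU-activated 1x1 affine transform of the source features
    (same shape as ``f_src``)."""
    f = _values(f_src)
    if f.shape[1] != p.src_channels:
        raise ValueError(f"feature has {f.shape[1]} channels, "
                         f"transform expects {p.src_channels}")
    return f.conv2d(p.U, p.e).gelu()


def gate_message(f_src, p: GateParams) -> Tensor:
    """The gated message ``x (x) o`` (before adding to the destination)."""
    x = gate_weight(f_src, p)                   # (N, C)
    o = transform(f_src, p)                     # (N, C, H, W)
    msg = x.reshape(x.shape[0], x.shape[1], 1, 1) * o
    if p.proj is not None:
        msg = p.proj(msg)
    return msg


def fuse(f_src, f_dst, p: GateParams) -> Tensor:
    """``f_dst + x (x) o`` — gated message passing from source into
    destination.  Differentiable w.r.t. the gate parameters and both
    feature maps."""
    src, dst = _values(f_src), _values(f_dst)
    if dst.shape[1] != p.dst_channels:
        raise ValueError(f"destination has {dst.shape[1]} channels, "
                         f"fusion expects {p.dst_channels}")
    if src.shape[-2:] != dst.shape[-2:]:
        raise ValueError("source and destination spatial sizes differ")
    return dst + gate_message(f_src, p)


def bidirectional_fuse(f_main, f_aux, p_ma: GateParams,
                       p_am: GateParams) -> tuple[Tensor, Tensor]:
    """Simultaneous two-way fusion from PRE-fusion features.

    ``p_ma`` carries main -> aux, ``p_am`` carries aux -> main.  Equals two
    independent :func:`fuse` calls on the original inputs.
    """
    if isinstance(f_main, FeatureMap) and isinstance(f_aux, FeatureMap):
        if f_main.stage != f_aux.stage:
            raise ValueError(
                f"stage mismatch: main stage {f_main.stage} vs aux {f_aux.stage}")
    new_main = fuse(f_aux, f_main, p_am)
    new_aux = fuse(f_main, f_aux, p_ma)
    return new_main, new_aux


# ---------------------------------------------------------------------------
# gate-learnability experiment
# ---------------------------------------------------------------------------

def gate_suppression_experiment(seed: int, steps: int = 200,
                                channels: int = 4, spatial: int = 4,
                                batch: int = 16,
                                lr: float = 0.05) -> tuple[float, float]:
    """Train a single fusion point whose source branch carries pure noise.

    Branch b's regression target depends only on branch b's own features,
    so the loss is minimized by suppressing the cross-branch message.
    Returns the mean message magnitude ``mean |x (x) o|`` before and after
    ``steps`` gradient steps; a learnable gate drives the final value
    below the initial one.
    """
    from .nn import SGD, Linear

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    gate = GateParams(channels, rng=rng, init_scale=0.3)
    head = Linear(channels, 1, rng)
    readout = rng.normal(0.0, 1.0, size=channels)   # defines the target

    def batch_data():
        f_b = rng.normal(0.0, 1.0, size=(batch, channels, spatial, spatial))
        f_a = rng.normal(0.0, 1.0, size=(batch, channels, spatial, spatial))
        target = (f_b.mean(axis=(2, 3)) @ readout)[:, None]
        return Tensor(f_a), Tensor(f_b), Tensor(target)

    def message_magnitude() -> float:
        f_a, _, _ = batch_data()
        return float(np.abs(gate_message(f_a, gate).data).mean())

    initial = message_magnitude()
    opt = SGD({"all": (gate.parameters() + head.parameters(), lr)})
    for _ in range(steps):
        f_a, f_b, target = batch_data()
        fused = fuse(f_a, f_b, gate)
        pred = head(fused.mean(axis=(2, 3)))
        loss = ((pred - target) ** 2.0).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    final = message_magnitude()
    return initial, final
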