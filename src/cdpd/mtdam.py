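"""Dual-branch multi-task training (MT-DAM).

A detection *main* branch and a segmentation *auxiliary* branch run in
parallel over backbones with equal stage counts; after every backbone
stage the two feature maps exchange information through a pair of
adaptive gates (:mod:`cdpd.dag_fusion`).  The main head is a minimal
anchor-free detector: each cell of the final feature grid predicts a box
(sigmoid-bounded centre offset and size), an objectness score and
per-class probabilities.  The auxiliary head predicts a per-pixel
foreground probability map.

Training minimizes

    L_total = L_main + lambda_train * L_aux

where ``L_main`` is class BCE over positives + (1 - mean IoU of matched
boxes) + objectness BCE over all cells, and ``L_aux`` is the Dice loss
``1 - 2*sum(p t) / (sum(p^2) + sum(t^2))``.  Main, auxiliary and gate
parameters live in one optimizer; the gate group has its own learning
rate.

Matching: for evaluation and test-time adaptation, predictions are
matched to boxes greedily by IoU at a threshold (default 0.5, lower
prediction index breaks ties).  During training each target is assigned
to the grid cell containing its centre — the standard one-stage
assignment — so gradients flow from the first step even when no
prediction yet clears the IoU threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .dag_fusion import GateParams, bidirectional_fuse
from .dynamic_augmentation import scenes_to_batch
from .nn import SGD, Conv2d, Module
from .synthetic_scenes import LabeledScene

__all__ = [
    "TrainConfig", "Detections", "DualBranchModel", "ConvStage",
    "make_toy_backbone", "make_dual_branch_model", "forward_fused",
    "iou", "iou_matrix", "iou_pairs", "match_boxes", "cell_assignment",
    "detection_train_loss", "dice_loss", "total_train_loss",
    "train_step", "train", "nms_detections",
]

_EPS = 1e-7

# fixed inference-time NMS operating point
NMS_IOU = 0.5
NMS_SCORE = 0.25


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    image_size: int = 416
    batch_size: int = 32
    lr_init: float = 0.05
    lr_final: float = 0.1
    dag_lr: float = 0.02
    lambda_train: float = 1.0
    momentum: float = 0.9
    schedule: str = "linear"       # "linear" (as-configured endpoints) | "cosine"
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_init, self.lr_final, self.dag_lr) <= 0:
            raise ValueError("all learning rates must be > 0")
        if self.schedule not in ("linear", "cosine"):
            raise ValueError("schedule must be 'linear' or 'cosine'")

    def lr_at(self, epoch: int) -> float:
        warmup = max(1, self.epochs // 20)   # linear ramp over the first 5%
        if epoch < warmup:
            return self.lr_init * (epoch + 1) / warmup
        t = (epoch - warmup) / max(1, self.epochs - 1 - warmup)
        if self.schedule == "linear":
            return self.lr_init + (self.lr_final - self.lr_init) * t
        return self.lr_final + 0.5 * (self.lr_init - self.lr_final) * (
            1.0 + math.cos(math.pi * t))


@dataclass
class Detections:
    """Per-image detector output: one candidate per feature-grid cell."""

    boxes: Tensor          # (M, 4) half-open pixel boxes
    class_probs: Tensor    # (M, K) in [0, 1]
    confidence: Tensor     # (M,) in [0, 1]

    def numpy(self) -> dict:
        return {"boxes": self.boxes.data.copy(),
                "class_probs": self.class_probs.data.copy(),
                "confidence": self.confidence.data.copy()}

    def nms(self, iou_thresh: float = NMS_IOU,
            score_thresh: float = NMS_SCORE) -> dict:
        return nms_detections(self.boxes.data, self.confidence.data,
                              self.class_probs.data, iou_thresh, score_thresh)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def iou(box_a, box_b) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union) if union > 0 else 0.0


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs IoU, (P, T)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0.0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0.0)
    inter = iw * ih
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    union = area_a + area_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def iou_pairs(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable IoU of paired boxes, (M,)."""
    zero = Tensor(0.0)
    iw = (a[:, 2].minimum(b[:, 2]) - a[:, 0].maximum(b[:, 0])).maximum(zero)
    ih = (a[:, 3].minimum(b[:, 3]) - a[:, 1].maximum(b[:, 1])).maximum(zero)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a + area_b - inter
    return inter / (union + 1e-12)


def match_boxes(pred_boxes: np.ndarray, target_boxes: np.ndarray,
                iou_threshold: float = 0.5) -> list[tuple[int, int]]:
    """Greedy highest-IoU one-to-one matching.

    Pairs below the threshold stay unmatched; ties are broken by lower
    prediction index, then lower target index.  Returns (pred, target)
    index pairs.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=np.float64).reshape(-1, 4)
    target_boxes = np.asarray(target_boxes, dtype=np.float64).reshape(-1, 4)
    if len(pred_boxes) == 0 or len(target_boxes) == 0:
        return []
    mat = iou_matrix(pred_boxes, target_boxes)
    candidates = [(-mat[p, t], p, t)
                  for p in range(mat.shape[0]) for t in range(mat.shape[1])
                  if mat[p, t] >= iou_threshold]
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, p, t in candidates:
        if p in used_p or t in used_t:
            continue
        pairs.append((p, t))
        used_p.add(p)
        used_t.add(t)
    return pairs


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class ConvStage(Module):
    """One backbone stage: 3x3 stride-2 convolution + leaky ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, 3, rng, stride=2, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).leaky_relu()


class DetHead(Module):
    """Anchor-free detection head: hidden 3x3 conv then 1x1 to (5+K)."""

    def __init__(self, cin: int, num_classes: int, rng: np.random.Generator):
        self.hidden = Conv2d(cin, 2 * cin, 3, rng, stride=1, padding=1)
        self.out = Conv2d(2 * cin, 5 + num_classes, 1, rng)
        self.out.bias.data[4] = -2.0   # objectness prior: most cells are empty

    def forward(self, f: Tensor) -> Tensor:
        return self.out(self.hidden(f).leaky_relu())


class SegDecoder(Module):
    """Mask head: merges the (post-fusion) aux feature pyramid top-down.

    Each stage feature is projected to a common width by a 1x1 conv; the
    deepest map is upsampled and added to the next-shallower projection
    with a 3x3 conv in between, ending with a final upsample to full
    resolution and a 1x1 logit conv.  The pyramid gives the per-pixel
    head access to higher-resolution detail than the last stage alone.
    """

    def __init__(self, channels: list[int], rng: np.random.Generator,
                 width: int = 8):
        self.projs = [Conv2d(c, width, 1, rng) for c in channels]
        self.mixes = [Conv2d(width, width, 3, rng, stride=1, padding=1)
                      for _ in channels[:-1]]
        self.full = Conv2d(width, width, 3, rng, stride=1, padding=1)
        self.out = Conv2d(width, 1, 1, rng)
        self.out.bias.data[0] = -2.0   # foreground prior: most pixels background

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        # pyramid[0] is the shallowest (highest-resolution) stage output
        h = self.projs[-1](pyramid[-1])
        for proj, mix, feat in zip(self.projs[-2::-1], self.mixes[::-1],
                                   pyramid[-2::-1]):
            h = h.repeat_nearest(2) + proj(feat)
            h = mix(h).leaky_relu()
        h = self.full(h.repeat_nearest(2)).leaky_relu()  # full-res sharpening
        return self.out(h)


def make_toy_backbone(stages: int, channels: list[int],
                      seed: int, in_channels: int = 3) -> list[ConvStage]:
    """Small deterministic convolutional backbone used throughout the tests."""
    if stages < 2:
        raise ValueError("need at least 2 stages")
    if len(channels) != stages:
        raise ValueError("one channel count per stage")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    out = []
    cin = in_channels
    for cout in channels:
        out.append(ConvStage(cin, cout, rng))
        cin = cout
    return out


class DualBranchModel(Module):
    """Detection main branch + segmentation aux branch with DAG fusion."""

    def __init__(self, num_classes: int, image_size: int,
                 main_stages: list[ConvStage], aux_stages: list[ConvStage],
                 seed: int = 0, gate_init_scale: float = 0.05):
        if len(main_stages) != len(aux_stages):
            raise ValueError("branches must have equal stage counts")
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed + 1))
        self.num_classes = num_classes
        self.image_size = image_size
        self.main_stages = main_stages
        self.aux_stages = aux_stages
        self.gates_ma = []   # main -> aux, one per stage
        self.gates_am = []   # aux -> main
        for ms, as_ in zip(main_stages, aux_stages):
            c_main = ms.conv.weight.shape[0]
            c_aux = as_.conv.weight.shape[0]
            self.gates_ma.append(GateParams(c_main, c_aux, rng, gate_init_scale))
            self.gates_am.append(GateParams(c_aux, c_main, rng, gate_init_scale))
        c_last_main = main_stages[-1].conv.weight.shape[0]
        aux_channels = [s.conv.weight.shape[0] for s in aux_stages]
        self.main_head = DetHead(c_last_main, num_classes, rng)
        self.aux_head = SegDecoder(aux_channels, rng)
        self.up_factor = 2 ** len(main_stages)
        if image_size % self.up_factor:
            raise ValueError(f"image_size must be divisible by {self.up_factor}")
        self.grid = image_size // self.up_factor

    # parameter groups -------------------------------------------------------
    def main_parameters(self) -> list[Tensor]:
        ps = []
        for s in self.main_stages:
            ps.extend(s.parameters())
        ps.extend(self.main_head.parameters())
        return ps

    def aux_parameters(self) -> list[Tensor]:
        ps = []
        for s in self.aux_stages:
            ps.extend(s.parameters())
        ps.extend(self.aux_head.parameters())
        return ps

    def dag_parameters(self) -> list[Tensor]:
        ps = []
        for g in self.gates_ma + self.gates_am:
            ps.extend(g.parameters())
        return ps

    def zero_fusion(self):
        """Zero every gate transform: fusion becomes an exact no-op."""
        for g in self.gates_ma + self.gates_am:
            g.zero_transform()

    # forward ----------------------------------------------------------------
    def forward(self, images: Tensor, fusion: bool = True
                ) -> tuple[list[Detections], Tensor]:
        n = images.shape[0]
        if images.shape[2] != self.image_size or images.shape[3] != self.image_size:
            raise ValueError(f"expected {self.image_size}x{self.image_size} input")
        f_main = f_aux = images
        aux_pyramid: list[Tensor] = []
        for k, (ms, as_) in enumerate(zip(self.main_stages, self.aux_stages)):
            f_main = ms(f_main)
            f_aux = as_(f_aux)
            if not np.all(np.isfinite(f_main.data)) or \
               not np.all(np.isfinite(f_aux.data)):
                raise FloatingPointError(f"non-finite activations at stage {k}")
            if fusion:
                f_main, f_aux = bidirectional_fuse(
                    f_main, f_aux, self.gates_ma[k], self.gates_am[k])
            aux_pyramid.append(f_aux)
        raw = self.main_head(f_main)                   # (N, 5+K, S, S)
        dets = self._decode(raw)
        mask_logit = self.aux_head(aux_pyramid)        # (N, 1, H, W)
        mask = mask_logit.sigmoid()
        mask = mask.reshape(n, self.image_size, self.image_size)
        return dets, mask

    def _decode(self, raw: Tensor) -> list[Detections]:
        n, _, s, _ = raw.shape
        stride = self.image_size / s
        cols = Tensor(np.tile(np.arange(s, dtype=np.float64), (s, 1)))
        rows = Tensor(np.tile(np.arange(s, dtype=np.float64)[:, None], (1, s)))
        # centre offsets are sigmoid-bounded to the cell; sizes use softplus
        # (in stride units) so large boxes keep a usable gradient
        cx = (raw[:, 0].sigmoid() + cols) * stride
        cy = (raw[:, 1].sigmoid() + rows) * stride
        bw = raw[:, 2].softplus() * stride
        bh = raw[:, 3].softplus() * stride
        half_w, half_h = bw * 0.5, bh * 0.5
        boxes = ad.stack([cx - half_w, cy - half_h, cx + half_w, cy + half_h],
                         axis=-1).reshape(n, s * s, 4)
        conf = raw[:, 4].sigmoid().reshape(n, s * s)
        cls = raw[:, 5:].sigmoid().transpose(0, 2, 3, 1).reshape(
            n, s * s, self.num_classes)
        return [Detections(boxes=boxes[i], class_probs=cls[i],
                           confidence=conf[i]) for i in range(n)]


def make_dual_branch_model(num_classes: int, image_size: int = 48,
                           stages: int = 3, channels: tuple = (8, 16, 16),
                           seed: int = 0) -> DualBranchModel:
    main = make_toy_backbone(stages, list(channels), seed)
    aux = make_toy_backbone(stages, list(channels), seed + 1000)
    return DualBranchModel(num_classes, image_size, main, aux, seed=seed)


def forward_fused(model: DualBranchModel, images: Tensor,
                  fusion: bool = True) -> tuple[list[Detections], Tensor]:
    """Run both backbones stage-by-stage with bidirectional fusion after
    each stage; heads consume the final fused features."""
    return model.forward(images, fusion=fusion)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def detection_train_loss(pred: Detections, target: LabeledScene,
                         pairing: list[tuple[int, int]] | None = None,
                         iou_threshold: float = 0.5) -> Tensor:
    """Class BCE over positives + (1 - mean matched IoU) + objectness BCE.

    ``pairing`` is a list of (prediction index, target index) pairs; when
    omitted it is computed by greedy IoU matching.  With no matched pairs
    the IoU term takes its worst-case value 1.
    """
    if pairing is None:
        pairing = match_boxes(pred.boxes.data, target.boxes, iou_threshold)

    k = pred.class_probs.shape[1]
    n_pred = pred.boxes.shape[0]

    if pairing:
        pis = np.asarray([p for p, _ in pairing])
        tis = np.asarray([t for _, t in pairing])
        probs = pred.class_probs[pis].clip(_EPS, 1.0 - _EPS)
        onehot = np.zeros((len(pairing), k))
        onehot[np.arange(len(pairing)), target.class_ids[tis]] = 1.0
        y = Tensor(onehot)
        cls_term = -(y * probs.log()
                     + (1.0 - y) * (1.0 - probs).log()).sum(axis=1).mean()
        tgt_boxes = Tensor(target.boxes[tis])
        iou_term = 1.0 - iou_pairs(pred.boxes[pis], tgt_boxes).mean()
    else:
        cls_term = Tensor(0.0)
        iou_term = Tensor(1.0)   # worst case by convention

    y_conf = np.zeros(n_pred)
    if pairing:
        y_conf[[p for p, _ in pairing]] = 1.0
    conf = pred.confidence.clip(_EPS, 1.0 - _EPS)
    yc = Tensor(y_conf)
    conf_term = -(yc * conf.log() + (1.0 - yc) * (1.0 - conf).log()).mean()

    return cls_term + iou_term + conf_term


def dice_loss(p: Tensor, t: np.ndarray) -> Tensor:
    """Dice loss ``1 - 2*sum(pt) / (sum(p^2) + sum(t^2))``; 0 when both
    prediction and target are empty."""
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    t_sq = float((t * t).sum())
    p_sq = (p ** 2.0).sum()
    if float(p_sq.data) + t_sq == 0.0:
        return Tensor(0.0)
    num = 2.0 * (p * Tensor(t)).sum()
    return 1.0 - num / (p_sq + t_sq)


def total_train_loss(l_main: Tensor, l_aux: Tensor, lambda_train: float) -> Tensor:
    """Weighted sum ``L_main + lambda_train * L_aux``."""
    return l_main + lambda_train * l_aux


def cell_assignment(target: LabeledScene, grid: int,
                    image_size: int) -> list[tuple[int, int]]:
    """Training-time assignment: each target goes to the grid cell holding
    its centre (first target wins a contested cell)."""
    stride = image_size / grid
    pairs = []
    used: set[int] = set()
    for ti, (x0, y0, x1, y1) in enumerate(target.boxes):
        col = min(grid - 1, int(((x0 + x1) / 2) / stride))
        row = min(grid - 1, int(((y0 + y1) / 2) / stride))
        cell = row * grid + col
        if cell in used:
            continue
        used.add(cell)
        pairs.append((cell, ti))
    return pairs


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def make_optimizer(model: DualBranchModel, cfg: TrainConfig) -> SGD:
    return SGD({
        "main": (model.main_parameters(), cfg.lr_init),
        "aux": (model.aux_parameters(), cfg.lr_init),
        "dag": (model.dag_parameters(), cfg.dag_lr),
    }, momentum=cfg.momentum, max_grad_norm=5.0)


def train_step(model: DualBranchModel, batch: list[LabeledScene],
               cfg: TrainConfig, opt: SGD) -> dict:
    """One shared-optimizer update from the combined dual-task loss."""
    images = scenes_to_batch(batch)
    dets, masks = forward_fused(model, images)
    det_losses, dice_losses = [], []
    for i, scene in enumerate(batch):
        pairing = cell_assignment(scene, model.grid, model.image_size)
        det_losses.append(detection_train_loss(dets[i], scene, pairing=pairing))
        dice_losses.append(dice_loss(masks[i], (scene.mask > 0).astype(float)))
    l_main = sum(det_losses[1:], det_losses[0]) / float(len(batch))
    l_aux = sum(dice_losses[1:], dice_losses[0]) / float(len(batch))
    total = total_train_loss(l_main, l_aux, cfg.lambda_train)
    opt.zero_grad()
    if np.isfinite(total.data):
        total.backward()
        stepped = opt.step()
    else:
        stepped = False
    return {"loss_main": float(l_main.data), "loss_aux": float(l_aux.data),
            "loss_total": float(total.data), "stepped": stepped}


def train(model: DualBranchModel, scenes: list[LabeledScene],
          cfg: TrainConfig, log_path=None) -> list[dict]:
    """Full training loop with the configured learning-rate schedule.

    Returns per-epoch records (mean losses, learning rates); optionally
    writes them as line-delimited JSON.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    opt = make_optimizer(model, cfg)
    history = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            lr = cfg.lr_at(epoch)
            opt.set_lr("main", lr)
            opt.set_lr("aux", lr)
            order = rng.permutation(len(scenes))
            records = []
            for start in range(0, len(scenes), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [scenes[i] for i in idx]
                records.append(train_step(model, batch, cfg, opt))
            rec = {"epoch": epoch, "lr": lr, "dag_lr": cfg.dag_lr,
                   "loss_main": float(np.mean([r["loss_main"] for r in records])),
                   "loss_aux": float(np.mean([r["loss_aux"] for r in records])),
                   "loss_total": float(np.mean([r["loss_total"] for r in records]))}
            history.append(rec)
            if log_file:
                log_file.write(json.dumps(rec) + "\n")
    finally:
        if log_file:
            log_file.close()
    return history


# ---------------------------------------------------------------------------
# inference-time NMS
# ---------------------------------------------------------------------------

def nms_detections(boxes: np.ndarray, conf: np.ndarray, class_probs: np.ndarray,
                   iou_thresh: float = NMS_IOU,
                   score_thresh: float = NMS_SCORE) -> dict:
    """Class-wise greedy non-maximum suppression.

    Score is objectness times the best class probability; boxes below
    ``score_thresh`` are dropped, then same-class overlaps above
    ``iou_thresh`` are suppressed in score order.
    """
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    conf = np.asarray(conf, dtype=np.float64).reshape(-1)
    class_probs = np.asarray(class_probs, dtype=np.float64)
    classes = class_probs.argmax(axis=1) if class_probs.size else np.zeros(0, int)
    best_p = class_probs.max(axis=1) if class_probs.size else np.zeros(0)
    scores = conf * best_p
    keep_mask = scores >= score_thresh
    idx = np.nonzero(keep_mask)[0]
    idx = idx[np.argsort(-scores[idx], kind="stable")]
    kept: list[int] = []
    for i in idx:
        ok = True
        for j in kept:
            if classes[i] == classes[j] and iou(boxes[i], boxes[j]) > iou_thresh:
                ok = False
                break
        if ok:
            kept.append(int(i))
    kept_arr = np.asarray(kept, dtype=int)
    return {"boxes": boxes[kept_arr].reshape(-1, 4),
            "scores": scores[kept_arr],
            "classes": classes[kept_arr],
            "confidence": conf[kept_arr],
            "class_probs": class_probs[kept_arr].reshape(-1, class_probs.shape[1])
            if class_probs.size else np.zeros((0, 0))}
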