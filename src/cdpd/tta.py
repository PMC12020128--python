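"""Continual test-time adaptation via pseudo-labels.

For every incoming test image the model generates ``num_variants``
photometric variants (additive Gaussian noise ``I + N(0, alpha^2)``,
brightness scaling ``L * I``, and the combination ``(I + B) + N(0,
alpha^2)``), runs each through the fused dual-branch model, and keeps
the highest-confidence result as the pseudo-label.  The loss of the
ORIGINAL image's predictions against that pseudo-label —

    L_total = (L_cls + L_loc + L_conf) + lambda * L_aux

with cross-entropy class loss over matched boxes, summed squared
differences of the (image-size-normalized) box parameters, objectness
BCE over all predictions, and per-pixel squared mask error (normalized
by H*W) — drives one online gradient step of the main and auxiliary
parameters.  Gate parameters stay frozen during adaptation by default
(``adapt_dag`` enables them); fusion itself remains active in every
forward pass.  Domains in a stream are processed in order without
weight resets, so adaptation state carries over — continual TTA.

All variants are intensity-only, so pseudo-label boxes live in the
original image geometry and need no coordinate remapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .evaluation import DomainSequenceResult, evaluate_detections, sequence_result
from .mtdam import (Detections, DualBranchModel, TrainConfig, forward_fused,
                    match_boxes, total_train_loss)
from .nn import SGD
from .synthetic_scenes import LabeledScene

__all__ = ["TTAConfig", "PseudoLabel", "generate_variants", "image_confidence",
           "select_pseudo_label", "tta_main_loss", "tta_aux_loss", "tta_step",
           "continual_adapt", "frozen_predictions"]

_EPS = 1e-7


@dataclass(frozen=True)
class TTAConfig:
    num_variants: int = 16
    noise_alpha: float = 12.0 / 255.0        # max Gaussian noise std on [0,1]
    brightness_factor_range: tuple = (0.7, 1.3)
    offset_range: tuple = (-0.3, 0.3)
    eta: float = 1e-4                        # online learning rate
    lam: float = 1.0                         # aux-loss weight
    adapt_dag: bool = False
    match_iou: float = 0.5
    # confidence gate: skip the online update when the selected pseudo-label
    # is empty or weaker than this, so self-training errors cannot
    # accumulate on images the model cannot label (PL/TENT-style collapse)
    min_confidence: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.num_variants < 1:
            raise ValueError("num_variants must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass
class PseudoLabel:
    """Highest-confidence result across variants, used as the self-training
    target.  Boxes are valid for the ORIGINAL image geometry."""

    boxes: np.ndarray         # (M, 4)
    class_ids: np.ndarray     # (M,)
    class_probs: np.ndarray   # (M, K)
    conf: np.ndarray          # (M,)
    mask: np.ndarray          # (H, W) binary
    source_variant: int
    source_model: str = "main"


def generate_variants(image: np.ndarray, cfg: TTAConfig,
                      seed: int | None = None) -> list[np.ndarray]:
    """Exactly ``cfg.num_variants`` photometric variants of ``image``.

    Slots are split into noise-only, brightness-only, and combined
    (roughly 5/5/6 at the default 16), with parameters on deterministic
    uniform grids and seeded noise draws.  All outputs are clipped to
    [0, 1]; geometry is untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed if seed is None else seed))
    n = cfg.num_variants
    n_noise = max(1, round(n * 5 / 16))
    n_bright = max(0, round(n * 5 / 16))
    n_combo = n - n_noise - n_bright

    variants: list[np.ndarray] = []
    alphas = np.linspace(cfg.noise_alpha / n_noise, cfg.noise_alpha, n_noise)
    for a in alphas:
        variants.append(np.clip(image + rng.normal(0.0, a, image.shape), 0, 1)
                        if a > 0 else image.copy())
    if n_bright:
        for L in np.linspace(*cfg.brightness_factor_range, n_bright):
            variants.append(np.clip(L * image, 0.0, 1.0))
    if n_combo > 0:
        a = cfg.noise_alpha / 2.0
        for B in np.linspace(*cfg.offset_range, n_combo):
            noisy = image + B + rng.normal(0.0, a, image.shape) if a > 0 \
                else image + B
            variants.append(np.clip(noisy, 0.0, 1.0))
    return variants


def image_confidence(det: dict) -> float:
    """Mean per-box confidence of a post-NMS result; 0 with no boxes."""
    conf = np.asarray(det.get("confidence", det.get("scores", [])))
    return float(conf.mean()) if conf.size else 0.0


def select_pseudo_label(variant_results: list[tuple[dict, np.ndarray]]
                        ) -> PseudoLabel:
    """Argmax of image confidence across variant results.

    ``variant_results[v]`` is the post-NMS detection dict and the aux mask
    probability map for variant ``v``.  Ties go to the lowest variant
    index (and the main model's detections always provide the box-type
    pseudo-label, the winning variant's aux output the mask).  The mask is
    binarized at 0.5.
    """
    if not variant_results:
        raise ValueError("need at least one variant result")
    confidences = [image_confidence(det) for det, _ in variant_results]
    best = int(np.argmax(confidences))   # argmax takes the first maximum
    det, mask = variant_results[best]
    classes = np.asarray(det["classes"], dtype=np.int64)
    return PseudoLabel(
        boxes=np.asarray(det["boxes"], dtype=np.float64).reshape(-1, 4),
        class_ids=classes,
        class_probs=np.asarray(det["class_probs"], dtype=np.float64),
        conf=np.asarray(det["confidence"], dtype=np.float64),
        mask=(np.asarray(mask) >= 0.5).astype(np.float64),
        source_variant=best, source_model="main")


# ---------------------------------------------------------------------------
# pseudo-label losses
# ---------------------------------------------------------------------------

def tta_main_loss(pred: Detections, pl: PseudoLabel, image_size: int,
                  match_iou: float = 0.5, ignore_above: float = 0.25,
                  pairing: list[tuple[int, int]] | None = None,
                  include: np.ndarray | None = None) -> Tensor:
    """Self-training detection loss against the pseudo-label.

    Cross-entropy of class probabilities against pseudo-class one-hots
    over matched pairs, plus summed squared differences of the four box
    parameters (normalized by image size), plus objectness BCE with
    matched-to-confident-pseudo-box targets.

    The objectness sum runs over matched predictions and over unmatched
    predictions whose own confidence is below ``ignore_above``.  A
    confident unmatched prediction is ambiguous — the pseudo-label may
    simply have missed that object — so it is excluded rather than pushed
    toward zero; otherwise every pseudo-label miss would erode genuine
    detections over a long adaptation stream.

    ``pairing`` and ``include`` may be supplied to evaluate the loss on a
    fixed surface (e.g. before/after one update step); by default both
    are derived from the current (detached) predictions.
    """
    if pairing is None:
        pairing = match_boxes(pred.boxes.data, pl.boxes, match_iou)
    k = pred.class_probs.shape[1]
    n_pred = pred.boxes.shape[0]

    if pairing:
        pis = np.asarray([p for p, _ in pairing])
        tis = np.asarray([t for _, t in pairing])
        probs = pred.class_probs[pis].clip(_EPS, 1.0 - _EPS)
        onehot = np.zeros((len(pairing), k))
        onehot[np.arange(len(pairing)), pl.class_ids[tis]] = 1.0
        cls_term = -(Tensor(onehot) * probs.log()).sum()
        diff = (pred.boxes[pis] - Tensor(pl.boxes[tis])) * (1.0 / image_size)
        loc_term = (diff ** 2.0).sum()
    else:
        cls_term = Tensor(0.0)
        loc_term = Tensor(0.0)

    y_conf = np.zeros(n_pred)
    if include is None:
        include = pred.confidence.data < ignore_above
        if pairing:
            include = include.copy()
            include[np.asarray([p for p, _ in pairing])] = True
    if pairing:
        pis = np.asarray([p for p, _ in pairing])
        tis = np.asarray([t for _, t in pairing])
        confident = pl.conf[tis] >= 0.5
        y_conf[pis[confident]] = 1.0
    conf = pred.confidence.clip(_EPS, 1.0 - _EPS)
    yc = Tensor(y_conf)
    mask = Tensor(include.astype(np.float64))
    conf_term = -(mask * (yc * conf.log()
                          + (1.0 - yc) * (1.0 - conf).log())).sum()

    return cls_term + loc_term + conf_term


def tta_aux_loss(mask_probs: Tensor, pl: PseudoLabel) -> Tensor:
    """Per-pixel squared error against the pseudo-mask, normalized by the
    pixel count so the aux weight is resolution-independent."""
    if mask_probs.shape != pl.mask.shape:
        raise ValueError(f"shape mismatch: {mask_probs.shape} vs {pl.mask.shape}")
    return ((mask_probs - Tensor(pl.mask)) ** 2.0).mean()


# ---------------------------------------------------------------------------
# online adaptation
# ---------------------------------------------------------------------------

def _predict(model: DualBranchModel, image: np.ndarray):
    """No-grad fused forward of a single (H, W, 3) image."""
    x = Tensor(image.transpose(2, 0, 1)[None])
    with no_grad():
        dets, masks = forward_fused(model, x)
        return dets[0], masks[0]


def tta_step(model: DualBranchModel, image: np.ndarray, cfg: TTAConfig,
             opt: SGD | None = None, seed: int | None = None
             ) -> tuple[DualBranchModel, dict, np.ndarray]:
    """One adaptation step on a single test image.

    Generates variants, forward-fuses each, selects the pseudo-label,
    computes ``L_total`` on the ORIGINAL image's predictions, and updates
    the main and auxiliary parameters (gates only if ``cfg.adapt_dag``).
    Returns the post-update prediction (post-NMS dict) and mask for the
    original image.  A non-finite loss skips the update but still returns
    a prediction.
    """
    if opt is None:
        opt = make_tta_optimizer(model, cfg)

    variants = generate_variants(image, cfg, seed=seed)
    batch = Tensor(np.stack([v.transpose(2, 0, 1) for v in variants]))
    with no_grad():
        dets, masks = forward_fused(model, batch)
        results = [(dets[v].nms(), masks.data[v]) for v in range(len(variants))]
    pl = select_pseudo_label(results)
    pl_confidence = float(pl.conf.mean()) if pl.conf.size else 0.0

    if cfg.eta > 0 and pl_confidence >= cfg.min_confidence:
        x = Tensor(image.transpose(2, 0, 1)[None])
        dets_orig, masks_orig = forward_fused(model, x)
        l_main = tta_main_loss(dets_orig[0], pl, model.image_size, cfg.match_iou)
        l_aux = tta_aux_loss(masks_orig[0], pl)
        total = total_train_loss(l_main, l_aux, cfg.lam)
        if np.isfinite(total.data):
            opt.zero_grad()
            total.backward()
            opt.step()

    det_after, mask_after = _predict(model, image)
    return model, det_after.nms(), mask_after.data.copy()


def make_tta_optimizer(model: DualBranchModel, cfg: TTAConfig) -> SGD:
    groups = {"main": (model.main_parameters(), cfg.eta),
              "aux": (model.aux_parameters(), cfg.eta)}
    if cfg.adapt_dag:
        groups["dag"] = (model.dag_parameters(), cfg.eta)
    return SGD(groups)


def continual_adapt(model: DualBranchModel,
                    stream: list[tuple[str, list[LabeledScene]]],
                    cfg: TTAConfig,
                    collect_predictions: bool = False):
    """Process an ordered domain stream WITHOUT weight resets.

    Returns a :class:`DomainSequenceResult` (and, optionally, the raw
    per-domain predictions).  Per-image pseudo-label selection and a
    fresh variant seed per image keep the run reproducible.
    """
    if not stream:
        raise ValueError("stream must be non-empty")
    opt = make_tta_optimizer(model, cfg)
    per_domain = {}
    preds_by_domain: dict[str, list[dict]] = {}
    for domain, scenes in stream:
        preds = []
        # variant seeds depend on (domain, image), not stream position, so
        # reordering domains changes results only through carried-over state
        dom_key = sum(ord(ch) for ch in domain)
        for i, scene in enumerate(scenes):
            seed = (cfg.seed * 100003 + dom_key * 1009 + i) % (2**31 - 1)
            _, det, _ = tta_step(model, scene.image, cfg, opt=opt, seed=seed)
            preds.append(det)
        preds_by_domain[domain] = preds
        per_domain[domain] = evaluate_detections(preds, scenes)
    result = sequence_result([d for d, _ in stream], per_domain)
    if collect_predictions:
        return result, preds_by_domain
    return result


def frozen_predictions(model: DualBranchModel,
                       scenes: list[LabeledScene]) -> list[dict]:
    """Plain (no-adaptation) post-NMS predictions for a scene list."""
    out = []
    for scene in scenes:
        det, _ = _predict(model, scene.image)
        out.append(det.nms())
    return out


# ---------------------------------------------------------------------------
# reference experiments
# ---------------------------------------------------------------------------

def tta_descent_check(model: DualBranchModel, images: list[np.ndarray],
                      cfg: TTAConfig) -> list[tuple[float, float]]:
    """For each image: L_total before and after one step, with the SAME
    pseudo-label.  A correct gradient step with small eta reduces it."""
    results = []
    for i, image in enumerate(images):
        variants = generate_variants(image, cfg, seed=cfg.seed + i)
        batch = Tensor(np.stack([v.transpose(2, 0, 1) for v in variants]))
        with no_grad():
            dets, masks = forward_fused(model, batch)
            vr = [(dets[v].nms(), masks.data[v]) for v in range(len(variants))]
        pl = select_pseudo_label(vr)

        # fix the matching and the objectness-inclusion mask from the
        # pre-step prediction so both evaluations share one loss surface
        x0 = Tensor(image.transpose(2, 0, 1)[None])
        with no_grad():
            d0, _ = forward_fused(model, x0)
        pairing = match_boxes(d0[0].boxes.data, pl.boxes, cfg.match_iou)
        include = d0[0].confidence.data < 0.25
        if pairing:
            include = include.copy()
            include[np.asarray([p for p, _ in pairing])] = True

        def loss_now():
            x = Tensor(image.transpose(2, 0, 1)[None])
            d, m = forward_fused(model, x)
            l = total_train_loss(
                tta_main_loss(d[0], pl, model.image_size, cfg.match_iou,
                              pairing=pairing, include=include),
                tta_aux_loss(m[0], pl), cfg.lam)
            return l

        before = loss_now()
        opt = make_tta_optimizer(model, cfg)
        opt.zero_grad()
        before.backward()
        opt.step()
        after = loss_now()
        results.append((float(before.data), float(after.data)))
    return results


def adaptation_benefit_experiment(seed: int, n_train: int = 40,
                                  n_stream: int = 32, kind: str = "DA",
                                  severity: float = 0.35, eta: float = 1e-3,
                                  epochs: int = 120, image_size: int = 48
                                  ) -> dict:
    """Scaled-down continual-adaptation experiment on a shifted stream.

    A toy dual-branch model is trained on clean synthetic scenes, then a
    brightness-shifted stream is processed online.  Returns mAP50 of the
    adapted and of the frozen model over the stream's last quartile.
    """
    from .mtdam import TrainConfig, make_dual_branch_model, train
    from .synthetic_scenes import CorruptionSpec, SceneSpec, apply_corruption, \
        generate_scene

    spec = SceneSpec(image_height=image_size, image_width=image_size,
                     objects_per_image=(1, 2), object_scale=(0.15, 0.28),
                     seed=seed * 2 + 11)
    train_scenes = [generate_scene(spec, i) for i in range(n_train)]
    stream_spec = SceneSpec(image_height=image_size, image_width=image_size,
                            objects_per_image=(1, 2), object_scale=(0.15, 0.28),
                            seed=seed * 2 + 12)
    stream_scenes = [
        apply_corruption(generate_scene(stream_spec, i),
                         CorruptionSpec(kind, severity, 100 * seed + i))
        for i in range(n_stream)]
    last_q = stream_scenes[3 * n_stream // 4:]

    cfg = TrainConfig(epochs=epochs, image_size=image_size, batch_size=8,
                      lr_init=0.04, lr_final=0.004, dag_lr=0.02,
                      schedule="cosine", seed=seed)
    model = make_dual_branch_model(spec.num_classes, image_size=image_size,
                                   seed=seed)
    train(model, train_scenes, cfg)
    state = model.state_dict()

    frozen = evaluate_detections(frozen_predictions(model, last_q), last_q)

    model.load_state_dict(state)
    tcfg = TTAConfig(eta=eta, seed=seed)
    opt = make_tta_optimizer(model, tcfg)
    preds = []
    for i, scene in enumerate(stream_scenes):
        _, det, _ = tta_step(model, scene.image, tcfg, opt=opt,
                             seed=1000 * (seed + 1) + i)
        preds.append(det)
    adapted = evaluate_detections(preds[3 * n_stream // 4:], last_q)
    return {"frozen_map50": frozen.map50, "tta_map50": adapted.map50,
            "clean_seed": seed}
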