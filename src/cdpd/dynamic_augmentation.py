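"""Learnable dynamic data augmentation (DynamicDA).

Two augmenters expand the training set sevenfold:

* A **strong augmenter** — a small residual encoder–decoder image-to-image
  network trained adversarially: a jointly trained K-class classifier keeps
  the augmented images classifiable (binary cross-entropy loss ``L_bce``)
  while two divergence losses push the outputs away from the originals
  (``L_dif``, per-pair mean squared difference to the source image) and away
  from each other within a batch (``L_bdf``, mean pairwise squared
  difference).  The generator parameters follow

      gamma <- gamma - alpha * grad( lambda_bce*L_bce
                                     - lambda_d*(lambda_dif*L_dif
                                                 + lambda_bdf*L_bdf) )

  so classification consistency is minimized while divergence is maximized.
  The outputs of the final ``retained_rounds`` training rounds form the
  strong-augmented dataset (3x the originals by default).

* A **weak augmenter** — fixed stochastic photometric jitter: Gaussian
  pixel noise with std drawn from ``sigma_levels`` (on the 0–255 scale) and
  a brightness transform ``beta*X + B``.  Three independent rounds triple
  the dataset.

All augmentations are photometric, so boxes, class ids and masks are
copied from the source scene unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Module
from .synthetic_scenes import LabeledScene

__all__ = [
    "StrongAugmenterState", "WeakAugmenterConfig", "AugmentedDataset",
    "ResidualGenerator", "SceneClassifier", "new_strong_augmenter",
    "strong_augment", "bce_loss", "dif_loss", "bdf_loss",
    "update_strong_augmenter", "train_strong_augmenter",
    "weak_augment_noise", "weak_augment_brightness",
    "build_augmented_datasets", "scenes_to_batch", "scene_class_labels",
]

_EPS = 1e-7  # probability clamp before logs


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class ResidualGenerator(Module):
    """Residual encoder-decoder: downsample, mix, upsample, add to input.

    The final convolution is initialized at a small scale so the untrained
    generator is near-identity and early strong augmentations remain
    label-preserving.
    """

    def __init__(self, channels: int = 8, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.down = Conv2d(3, channels, 3, rng, stride=2, padding=1)
        self.mix = Conv2d(channels, channels, 3, rng, stride=1, padding=1)
        self.up = Conv2d(channels, 3, 3, rng, stride=1, padding=1, scale=1e-3)

    def forward(self, x: Tensor) -> Tensor:
        h = self.down(x).leaky_relu()
        h = (h + self.mix(h).leaky_relu())  # residual block
        h = h.repeat_nearest(2)
        delta = self.up(h).tanh()
        return (x + delta).clip(0.0, 1.0)


class SceneClassifier(Module):
    """Small K-class multi-label image classifier (sigmoid outputs)."""

    def __init__(self, num_classes: int, channels: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(1)
        self.c1 = Conv2d(3, channels, 3, rng, stride=2, padding=1)
        self.c2 = Conv2d(channels, channels, 3, rng, stride=2, padding=1)
        from .nn import Linear
        self.head = Linear(channels, num_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).leaky_relu()
        h = self.c2(h).leaky_relu()
        pooled = h.mean(axis=(2, 3))            # global average pool -> (N, C)
        return self.head(pooled).sigmoid()       # (N, K) probabilities


@dataclass
class StrongAugmenterState:
    generator: ResidualGenerator
    classifier: SceneClassifier
    num_classes: int
    alpha: float = 0.01
    lambda_bce: float = 0.4
    lambda_d: float = 0.6
    lambda_dif: float = 0.5
    lambda_bdf: float = 0.5
    retained_rounds: int = 3
    retained: list = field(default_factory=list)   # list of (N,3,H,W) arrays

    def __post_init__(self):
        for name in ("lambda_bce", "lambda_d", "lambda_dif", "lambda_bdf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WeakAugmenterConfig:
    sigma_levels: tuple = (4.0, 8.0, 12.0, 16.0)   # noise std, 0-255 scale
    beta_range: tuple = (0.7, 1.3)
    offset_range: tuple = (-0.3, 0.3)
    rounds: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(s < 0 for s in self.sigma_levels):
            raise ValueError("sigma_levels must be >= 0")
        if self.beta_range[0] > self.beta_range[1]:
            raise ValueError("beta_range must be ordered")
        if self.offset_range[0] > self.offset_range[1]:
            raise ValueError("offset_range must be ordered")


@dataclass
class AugmentedDataset:
    original: list
    strong: list
    weak: list


def new_strong_augmenter(num_classes: int, seed: int = 0,
                         **overrides) -> StrongAugmenterState:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    return StrongAugmenterState(
        generator=ResidualGenerator(rng=rng),
        classifier=SceneClassifier(num_classes, rng=rng),
        num_classes=num_classes, **overrides)


# ---------------------------------------------------------------------------
# batch plumbing
# ---------------------------------------------------------------------------

def scenes_to_batch(scenes: list[LabeledScene]) -> Tensor:
    """Stack scene images into an (N, 3, H, W) tensor."""
    arr = np.stack([s.image.transpose(2, 0, 1) for s in scenes])
    return Tensor(arr)


def scene_class_labels(scenes: list[LabeledScene], num_classes: int) -> np.ndarray:
    """Multi-hot (N, K) presence labels: 1 where the class occurs in the scene."""
    labels = np.zeros((len(scenes), num_classes))
    for i, s in enumerate(scenes):
        for c in np.unique(s.class_ids):
            labels[i, int(c)] = 1.0
    return labels


def strong_augment(batch: Tensor, state: StrongAugmenterState) -> Tensor:
    """Run the strong augmenter on an (N, 3, H, W) batch in [0, 1]."""
    if batch.ndim != 4 or batch.shape[1] != 3:
        raise ValueError(f"expected (N,3,H,W) batch, got {batch.shape}")
    return state.generator(batch)


# ---------------------------------------------------------------------------
# the three losses
# ---------------------------------------------------------------------------

def bce_loss(probs: Tensor, labels) -> Tensor:
    """Binary cross-entropy averaged over every (image, class) entry.

    ``probs`` is (n, K) classifier output; ``labels`` a binary (n, K)
    array.  Probabilities are clamped to [eps, 1-eps] before the logs.
    """
    labels = labels if isinstance(labels, Tensor) else Tensor(labels)
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    p = probs.clip(_EPS, 1.0 - _EPS)
    terms = labels * p.log() + (1.0 - labels) * (1.0 - p).log()
    return -terms.mean()


def dif_loss(originals: Tensor, augments: Tensor) -> Tensor:
    """Sum over image pairs of the per-pixel mean squared difference."""
    if originals.shape != augments.shape:
        raise ValueError(f"shape mismatch: {originals.shape} vs {augments.shape}")
    diff = (originals - augments) ** 2.0
    per_image = diff.mean(axis=tuple(range(1, diff.ndim)))
    return per_image.sum()


def bdf_loss(augments: Tensor) -> Tensor:
    """Mean over unordered augmented-image pairs of the per-pixel MSE.

    ``2/(n(n-1)) * sum_{i<j} mse(aug_i, aug_j)``; 0 for n < 2 (the
    prefactor is undefined there and a degenerate batch must not crash).
    """
    n = augments.shape[0]
    if n < 2:
        return Tensor(0.0)
    total = None
    for i in range(n - 1):
        xi = augments[i]
        for j in range(i + 1, n):
            mse = ((xi - augments[j]) ** 2.0).mean()
            total = mse if total is None else total + mse
    return total * (2.0 / (n * (n - 1)))


# ---------------------------------------------------------------------------
# updates
# ---------------------------------------------------------------------------

def update_strong_augmenter(state: StrongAugmenterState, batch: Tensor,
                            labels: np.ndarray) -> Tensor:
    """One adversarial round: generator step then classifier step.

    The generator descends ``lambda_bce*L_bce - lambda_d*(lambda_dif*L_dif
    + lambda_bdf*L_bdf)``; the classifier separately minimizes ``L_bce``
    evaluated on both the augmented and the original images.  Returns the
    augmented batch produced this round (detached).
    """
    if batch.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    gen_params = state.generator.parameters()
    cls_params = state.classifier.parameters()

    # generator step
    aug = strong_augment(batch, state)
    probs = state.classifier(aug)
    objective = (state.lambda_bce * bce_loss(probs, labels)
                 - state.lambda_d * (state.lambda_dif * dif_loss(batch, aug)
                                     + state.lambda_bdf * bdf_loss(aug)))
    for p in gen_params + cls_params:
        p.grad = None
    objective.backward()
    if all(p.grad is None or np.all(np.isfinite(p.grad)) for p in gen_params):
        for p in gen_params:
            if p.grad is not None:
                p.data = p.data - state.alpha * p.grad
    else:
        warnings.warn("non-finite generator gradient; step skipped")

    aug_detached = aug.detach()

    # classifier step (frozen generator output + originals)
    stacked = ad.concatenate([aug_detached, batch.detach()], axis=0)
    both_labels = np.concatenate([labels, labels], axis=0)
    probs2 = state.classifier(stacked)
    cls_loss = bce_loss(probs2, both_labels)
    for p in cls_params:
        p.grad = None
    cls_loss.backward()
    if all(p.grad is None or np.all(np.isfinite(p.grad)) for p in cls_params):
        for p in cls_params:
            if p.grad is not None:
                p.data = p.data - state.alpha * p.grad
    else:
        warnings.warn("non-finite classifier gradient; step skipped")

    return aug_detached


def train_strong_augmenter(scenes: list[LabeledScene],
                           state: StrongAugmenterState,
                           rounds: int = 10) -> StrongAugmenterState:
    """Run ``rounds`` adversarial rounds, retaining the final few batches.

    The augmented images produced during the last ``state.retained_rounds``
    rounds are stored in ``state.retained`` and later become the
    strong-augmented dataset.
    """
    if rounds < state.retained_rounds:
        raise ValueError(
            f"need at least retained_rounds={state.retained_rounds} rounds")
    batch = scenes_to_batch(scenes)
    labels = scene_class_labels(scenes, state.num_classes)
    state.retained = []
    for r in range(rounds):
        aug = update_strong_augmenter(state, batch, labels)
        if r >= rounds - state.retained_rounds:
            state.retained.append(aug.data.copy())
    return state


# ---------------------------------------------------------------------------
# weak augmenter
# ---------------------------------------------------------------------------

def weak_augment_noise(image: np.ndarray, sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise of std ``sigma`` on the 0-255 scale
    (i.e. ``sigma/255`` on [0,1] images); clip to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    noisy = image + rng.normal(0.0, sigma / 255.0, size=image.shape)
    return np.clip(noisy, 0.0, 1.0)


def weak_augment_brightness(image: np.ndarray, beta: float,
                            offset: float) -> np.ndarray:
    """Brightness transform ``beta * X + B``, clipped to [0, 1]."""
    return np.clip(beta * image + offset, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_augmented_datasets(originals: list[LabeledScene],
                             state: StrongAugmenterState,
                             cfg: WeakAugmenterConfig) -> AugmentedDataset:
    """Assemble the combined training data: originals + 3x strong + 3x weak.

    Strong scenes are the retained final-round generator outputs; weak
    scenes are ``cfg.rounds`` independent passes, each drawing one noise
    level and one (beta, B) pair per image and applying brightness first,
    then noise.  Labels are copied from the source scenes.
    """
    if len(state.retained) < state.retained_rounds:
        raise ValueError(
            f"strong augmenter retained {len(state.retained)} rounds; "
            f"needs {state.retained_rounds} (train it first)")

    strong: list[LabeledScene] = []
    for round_images in state.retained[-state.retained_rounds:]:
        for scene, img in zip(originals, round_images):
            strong.append(scene.copy_with_image(
                np.clip(img.transpose(1, 2, 0), 0.0, 1.0)))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    weak: list[LabeledScene] = []
    for _ in range(cfg.rounds):
        for scene in originals:
            sigma = float(rng.choice(np.asarray(cfg.sigma_levels)))
            beta = rng.uniform(*cfg.beta_range)
            offset = rng.uniform(*cfg.offset_range)
            img = weak_augment_brightness(scene.image, beta, offset)
            img = weak_augment_noise(img, sigma, rng)
            weak.append(scene.copy_with_image(img))

    return AugmentedDataset(original=list(originals), strong=strong, weak=weak)
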