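"""Training protocol: split, flips, patch normalization, SGD schedule, MSE.

The protocol mirrors standard density-regression practice for counting:
a random 80/20 split of the dataset; online horizontal/vertical flip
augmentation (labels flip with the pixels, so counts are invariant);
per-patch standardization to zero mean and unit variance; and momentum
SGD on the mean squared error between the predicted and target density
surfaces, with the learning rate stepped down by a constant factor every
fixed number of epochs (0.01 divided by 10 every 10 epochs by default;
momentum 0.8, weight decay 0.005).

Density targets use unit-integral kernels multiplied by a global
``target_scale`` (default 100): per-pixel target magnitudes are otherwise
of order 1e-3, where float32 MSE gradients are poorly conditioned.
Counting divides the scale back out, so reported counts are unchanged.
All randomness (split, shuffling, augmentation draws) derives from
explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .density import KernelSpec, build_density_map
from .models import NetworkHandle
from .nn import F32, SGD, mse_loss
from .synthetic import AnnotatedImage, DotAnnotation

logger = logging.getLogger(__name__)

AUGMENT_MODES = ("none", "hflip", "vflip")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer, schedule, augmentation and split settings."""

    learning_rate: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 10
    momentum: float = 0.8
    weight_decay: float = 0.005
    epochs: int = 200
    batch_size: int = 1
    train_fraction: float = 0.8
    augment_flips: bool = True
    patch_size: int = 256
    target_scale: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if not self.lr_decay_factor > 1:
            raise ValueError(f"lr_decay_factor must be > 1, got {self.lr_decay_factor}")
        if self.lr_decay_every < 1:
            raise ValueError(f"lr_decay_every must be >= 1, got {self.lr_decay_every}")
        if not (0 < self.train_fraction < 1):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if not self.target_scale > 0:
            raise ValueError(f"target_scale must be > 0, got {self.target_scale}")


@dataclass
class TrainLog:
    """Per-epoch mean training loss and learning rate, plus the trained net."""

    losses: list[float]
    learning_rates: list[float]
    network: NetworkHandle

    def __post_init__(self):
        if len(self.losses) != len(self.learning_rates):
            raise ValueError("losses and learning_rates must have equal length")


def split_dataset(manifest, train_fraction: float, seed: int) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test partition of identifiers.

    ``manifest`` is a sequence of records with an ``identifier`` key (or a
    plain sequence of identifiers). ``|train| = round(train_fraction * N)``.
    """
    ids = [rec["identifier"] if isinstance(rec, dict) else rec for rec in manifest]
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    if not (0 < train_fraction < 1):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def augment(sample: AnnotatedImage, mode: str) -> AnnotatedImage:
    """Flip a sample and its dots together; ``mode`` in {none, hflip, vflip}.

    hflip mirrors columns (col -> width-1-col), vflip mirrors rows. Counts
    are unchanged, and each flip is an involution.
    """
    if mode not in AUGMENT_MODES:
        raise ValueError(f"mode must be one of {AUGMENT_MODES}, got {mode!r}")
    if mode == "none":
        return sample
    h, w = sample.annotation.frame_shape
    pts = sample.annotation.points.copy()
    if mode == "hflip":
        pixels = np.flip(sample.pixels, axis=1).copy()
        if pts.size:
            pts[:, 1] = (w - 1) - pts[:, 1]
    else:
        pixels = np.flip(sample.pixels, axis=0).copy()
        if pts.size:
            pts[:, 0] = (h - 1) - pts[:, 0]
    return AnnotatedImage(
        pixels=pixels,
        annotation=DotAnnotation(points=pts, frame_shape=(h, w)),
        identifier=sample.identifier,
    )


def extract_center_patch(sample: AnnotatedImage, patch_size: int) -> AnnotatedImage:
    """Central ``patch_size`` window; dots outside are dropped, the rest
    re-expressed in window coordinates."""
    h, w = sample.annotation.frame_shape
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} smaller than patch_size {patch_size}"
        )
    r0 = (h - patch_size) // 2
    c0 = (w - patch_size) // 2
    pixels = sample.pixels[r0 : r0 + patch_size, c0 : c0 + patch_size].copy()
    pts = sample.annotation.points
    if pts.size:
        shifted = pts - np.array([r0, c0])
        keep = (
            (shifted[:, 0] >= 0)
            & (shifted[:, 0] < patch_size)
            & (shifted[:, 1] >= 0)
            & (shifted[:, 1] < patch_size)
        )
        shifted = shifted[keep]
    else:
        shifted = pts
    return AnnotatedImage(
        pixels=pixels,
        annotation=DotAnnotation(points=shifted, frame_shape=(patch_size, patch_size)),
        identifier=sample.identifier,
    )


def normalize_patch(pixels: np.ndarray) -> np.ndarray:
    """Standardize a patch to zero mean and unit standard deviation.

    A constant patch (sd = 0) maps to all zeros rather than dividing by
    zero.
    """
    x = np.asarray(pixels, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty patch")
    mu = x.mean()
    sd = x.std()
    # constant patches can have sd ~ 1e-16 from mean round-off; treat as 0
    if sd <= 1e-12 * max(1.0, abs(mu)):
        return np.zeros_like(x)
    return (x - mu) / sd


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: lr / factor**floor(epoch / every), 0-based epoch."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch must be in [0, {config.epochs}), got {epoch}")
    return config.learning_rate / config.lr_decay_factor ** (epoch // config.lr_decay_every)


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    """Collapse RGB to luminance; pass grayscale through."""
    if pixels.ndim == 3:
        return pixels @ np.array([0.299, 0.587, 0.114])
    return pixels


def prepare_sample(sample: AnnotatedImage, patch_size: int) -> AnnotatedImage:
    """Grayscale conversion plus center-patch extraction when the image is
    larger than ``patch_size`` (images already at patch size pass through)."""
    gray = _to_gray(sample.pixels)
    if gray is not sample.pixels:
        sample = AnnotatedImage(gray, sample.annotation, sample.identifier)
    h, w = sample.annotation.frame_shape
    if h > patch_size or w > patch_size:
        sample = extract_center_patch(sample, min(patch_size, h, w))
    return sample


def train(
    network: NetworkHandle,
    samples: list[AnnotatedImage],
    kernel: KernelSpec,
    config: TrainConfig,
) -> TrainLog:
    """Fit the network to density targets with momentum SGD.

    Each epoch shuffles the training samples, draws one flip mode per
    sample (uniform over none/hflip/vflip when ``augment_flips``), and
    minimizes the MSE between the predicted map and ``target_scale`` times
    the unit-integral density target. Raises on non-finite loss, naming
    the epoch. Deterministic for fixed ``config.seed`` and inputs.
    """
    if not samples:
        raise ValueError("training set is empty")
    prepared = [prepare_sample(s, config.patch_size) for s in samples]
    target_kernel = replace(kernel, normalization="unit_integral")
    images = [normalize_patch(s.pixels).astype(F32) for s in prepared]
    targets = [
        (build_density_map(s.annotation, target_kernel).values * config.target_scale).astype(F32)
        for s in prepared
    ]

    rng = np.random.default_rng(config.seed)
    opt = SGD(network.net.params_grads(), momentum=config.momentum,
              weight_decay=config.weight_decay)
    n = len(prepared)
    losses: list[float] = []
    lrs: list[float] = []
    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n)
        if config.augment_flips:
            modes = rng.integers(0, 3, size=n)
        else:
            modes = np.zeros(n, dtype=int)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = np.empty((len(idx),) + images[0].shape + (1,), dtype=F32)
            tb = np.empty_like(xb)
            for b, i in enumerate(idx):
                x, t = images[i], targets[i]
                mode = modes[i]
                if mode == 1:  # hflip: density target of a flipped sample
                    x, t = x[:, ::-1], t[:, ::-1]  # equals the flipped target
                elif mode == 2:  # vflip
                    x, t = x[::-1], t[::-1]
                xb[b, :, :, 0] = x
                tb[b, :, :, 0] = t
            pred = network.net.forward(xb)
            loss, grad = mse_loss(pred, tb)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            network.net.backward(grad)
            opt.step(lr)
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        lrs.append(lr)
        logger.info("epoch %d/%d: loss %.6g, lr %g", epoch + 1, config.epochs,
                    losses[-1], lr)
    return TrainLog(losses=losses, learning_rates=lrs, network=network)
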