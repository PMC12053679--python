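"""Trainable encoder–decoder (U-Net) band segmentation.

The network follows the classic U-Net topology with a resnet18-pattern
encoder: a stem convolution followed by four down-sampling stages of basic
residual blocks (channel widths 64/128/256/512 at full width), skip
connections into a nearest-upsampling decoder, and a two-channel 1x1 output
head (channel 0 background, channel 1 band).  A ``width_multiplier`` scales
all channel counts down for CPU-scale experiments.

Training uses the recipe that works well for this task: combined soft-Dice
and cross-entropy loss with equal weights, Adam, a cosine-annealing
learning-rate schedule with warm restarts (1e-4 down to 1e-7, restart
period 100 epochs), batch size 2, random flip/rotation/blur/noise/
downscale/compression augmentation, and best-epoch selection by validation
Dice.  Implementation is pure NumPy (see :mod:`gelband.nn_layers`).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from gelband.classical import normalize01
from gelband.io import GelImage, SegmentationMask
from gelband.nn_layers import (
    Adam,
    Conv2d,
    ConvBNReLU,
    Param,
    ResidualBlock,
    Upsample2x,
    cosine_warm_restart_lr,
)

DEFAULT_AUGMENT_PROBS = {
    "flip": 0.5,
    "rotate": 0.5,
    "blur": 0.2,
    "noise": 0.2,
    "downscale": 0.2,
    "compression": 0.2,
}


@dataclass
class TrainingConfig:
    """Hyperparameters of the segmentation training loop."""

    batch_size: int = 2
    max_epochs: int = 600
    lr_init: float = 1e-4
    lr_min: float = 1e-7
    restart_period: int = 100
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (dice, cross-entropy)
    augment_probs: dict = field(default_factory=lambda: dict(DEFAULT_AUGMENT_PROBS))
    pad_multiple: int = 32
    seed: int = 0
    split_fracs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    width_multiplier: float = 1.0
    global_pad: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not self.lr_min < self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if self.pad_multiple < 1:
            raise ValueError("pad_multiple must be >= 1")


class UNet:
    """Encoder–decoder segmentation network (NumPy, manual backprop)."""

    def __init__(self, in_channels: int = 1, out_channels: int = 2,
                 width_multiplier: float = 1.0, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = max(int(round(64 * width_multiplier)), 4)
        self.base_width = b
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width_multiplier = width_multiplier
        self.seed = seed

        self.stem = ConvBNReLU(in_channels, b, 3, 1, rng)
        self.enc = [
            [ResidualBlock(b, b, 2, rng), ResidualBlock(b, b, 1, rng)],
            [ResidualBlock(b, 2 * b, 2, rng), ResidualBlock(2 * b, 2 * b, 1, rng)],
            [ResidualBlock(2 * b, 4 * b, 2, rng), ResidualBlock(4 * b, 4 * b, 1, rng)],
            [ResidualBlock(4 * b, 8 * b, 2, rng), ResidualBlock(8 * b, 8 * b, 1, rng)],
        ]
        self.up = [Upsample2x() for _ in range(4)]
        self.dec = [
            [ConvBNReLU(8 * b + 4 * b, 4 * b, 3, 1, rng), ConvBNReLU(4 * b, 4 * b, 3, 1, rng)],
            [ConvBNReLU(4 * b + 2 * b, 2 * b, 3, 1, rng), ConvBNReLU(2 * b, 2 * b, 3, 1, rng)],
            [ConvBNReLU(2 * b + b, b, 3, 1, rng), ConvBNReLU(b, b, 3, 1, rng)],
            [ConvBNReLU(b + b, b, 3, 1, rng), ConvBNReLU(b, b, 3, 1, rng)],
        ]
        self.head = Conv2d(b, out_channels, 1, 1, rng)
        self._skip_channels = [4 * b, 2 * b, b, b]

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        yield self.stem
        for stage in self.enc:
            yield from stage
        for stage in self.dec:
            yield from stage
        yield self.head

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for mod in self._modules():
            out.extend(mod.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays needed to restore the model (params + BN stats)."""
        arrays = [p.value for p in self.parameters()]
        for mod in self._modules():
            for attr in ("bn", "bn1", "bn2", "proj_bn"):
                bn = getattr(mod, attr, None)
                if bn is not None:
                    arrays.extend([bn.running_mean, bn.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(state):
            raise ValueError("checkpoint does not match this architecture")
        for tgt, src in zip(targets, state):
            np.copyto(tgt, src)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (N, C, H, W) with H, W divisible by 16 -> logits (N, 2, H, W)."""
        x = x.astype(np.float32)
        s0 = self.stem.forward(x, train)
        feats = [s0]
        h = s0
        for stage in self.enc:
            for block in stage:
                h = block.forward(h, train)
            feats.append(h)
        # feats: [s0 (/1), e1 (/2), e2 (/4), e3 (/8), e4 (/16)]
        skips = [feats[3], feats[2], feats[1], feats[0]]
        self._concat_splits = []
        for up, dec_stage, skip in zip(self.up, self.dec, skips):
            h = up.forward(h, train)
            h = np.concatenate([h, skip], axis=1)
            self._concat_splits.append(h.shape[1] - skip.shape[1])
            for block in dec_stage:
                h = block.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        # walk the decoder in reverse, collecting the gradients routed to the
        # skip connections: dskips ends up as [g_s0, g_e1, g_e2, g_e3]
        dskips = []
        for up, dec_stage, split in zip(
            reversed(self.up), reversed(self.dec), reversed(self._concat_splits)
        ):
            for block in reversed(dec_stage):
                d = block.backward(d)
            d_up, d_skip = d[:, :split], d[:, split:]
            dskips.append(d_skip)
            d = up.backward(d_up)
        # d is now the gradient at the deepest encoder output (e4)
        for idx, stage in enumerate(reversed(self.enc)):
            for block in reversed(stage):
                d = block.backward(d)
            d = d + dskips[3 - idx]
        self.stem.backward(d)

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train)


def build_model(
    in_channels: int = 1,
    out_channels: int = 2,
    width_multiplier: float = 1.0,
    seed: int = 0,
) -> UNet:
    """Build the encoder–decoder segmentation network.

    Two builds with the same seed have identical initial parameters.
    """
    return UNet(in_channels, out_channels, width_multiplier, seed)


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

def _pad_to_square_multiple(
    arr: np.ndarray, multiple: int, target: int | None = None
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    h, w = arr.shape
    side = max(h, w, target or 0)
    side = int(np.ceil(side / multiple) * multiple)
    dr, dc = side - h, side - w
    top, left = dr // 2, dc // 2
    pads = (top, dr - top, left, dc - left)  # extra pixel goes bottom/right
    padded = np.pad(arr, ((pads[0], pads[1]), (pads[2], pads[3])))
    return padded, pads


def prepare_input(
    image: GelImage,
    target_dims: int | None = None,
    pad_multiple: int = 32,
    pretreat: str = "raw",
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Normalise and zero-pad an image for the network.

    Intensities are divided by the maximum bit-type value (or percentile
    normalised when ``pretreat='percentile'``), then both dimensions are
    symmetrically zero-padded to the smallest multiple of ``pad_multiple``
    that is at least the largest input dimension (and ``target_dims``, if
    given), making the result square.  Odd pads put the extra pixel on the
    bottom/right.  Returns the padded array and the ``(top, bottom, left,
    right)`` pad record for exact crop-back.
    """
    if pretreat == "raw":
        img01 = normalize01(image)
    elif pretreat == "percentile":
        img01 = percentile_normalize(image)
    else:
        raise ValueError(f"unknown pretreat {pretreat!r}")
    return _pad_to_square_multiple(img01, pad_multiple, target_dims)


def crop_back(arr: np.ndarray, pads: tuple[int, int, int, int]) -> np.ndarray:
    """Undo :func:`prepare_input` padding on the trailing two axes."""
    top, bottom, left, right = pads
    sl_r = slice(top, arr.shape[-2] - bottom if bottom else None)
    sl_c = slice(left, arr.shape[-1] - right if right else None)
    return arr[..., sl_r, sl_c]


def percentile_normalize(image: GelImage, tail: float = 0.1) -> np.ndarray:
    """Clip at the ``tail``/``100 - tail`` intensity percentiles and map to [0, 1].

    The default removes the highest and lowest 0.1% of pixels before
    normalising, which makes inference robust to hot pixels and unusual
    exposure ranges.  A constant image yields all zeros with a warning.
    """
    pixels = image.pixels.astype(np.float64)
    low, high = np.percentile(pixels, [tail, 100.0 - tail])
    if high <= low:
        warnings.warn("constant image: percentile normalisation returns zeros")
        return np.zeros_like(pixels)
    return np.clip((pixels - low) / (high - low), 0.0, 1.0)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(
    image01: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    probs: dict | None = None,
    restricted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly augment a normalised image and its mask.

    Geometric operations (flip, rotation) apply identically to image and
    mask; photometric ones (blur, additive noise, downscale–upscale,
    compression-style quantisation) apply to the image only, with severities
    capped so band/background contrast is never reduced by more than about
    half.  ``restricted=True`` allows only flips and rotations (the
    fine-tuning regime).
    """
    probs = dict(DEFAULT_AUGMENT_PROBS if probs is None else probs)
    if restricted:
        probs = {k: (v if k in ("flip", "rotate") else 0.0) for k, v in probs.items()}
    img = image01.astype(np.float64)
    msk = (np.asarray(mask) > 0).astype(np.uint8)

    if rng.random() < probs.get("flip", 0):
        axis = int(rng.integers(0, 2))
        img = np.flip(img, axis=axis).copy()
        msk = np.flip(msk, axis=axis).copy()
    if rng.random() < probs.get("rotate", 0):
        k = int(rng.integers(0, 4))
        if k:
            img = np.rot90(img, k).copy()
            msk = np.rot90(msk, k).copy()
        angle = float(rng.uniform(-15.0, 15.0))
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="constant", cval=0)
        img = np.clip(img, 0.0, 1.0)
    if rng.random() < probs.get("blur", 0):
        img = ndimage.gaussian_filter(img, float(rng.uniform(0.3, 1.5)))
    if rng.random() < probs.get("noise", 0):
        img = np.clip(img + rng.normal(0.0, float(rng.uniform(0.005, 0.05)), img.shape), 0, 1)
    if rng.random() < probs.get("downscale", 0):
        factor = float(rng.uniform(0.5, 0.9))
        small = ndimage.zoom(img, factor, order=1)
        img = ndimage.zoom(small, np.array(img.shape) / np.array(small.shape), order=1)
        if img.shape != msk.shape:  # guard against rounding drift
            img = img[: msk.shape[0], : msk.shape[1]]
            img = np.pad(img, ((0, msk.shape[0] - img.shape[0]),
                               (0, msk.shape[1] - img.shape[1])), mode="edge")
    if rng.random() < probs.get("compression", 0):
        levels = int(rng.integers(16, 64))
        img = np.round(img * (levels - 1)) / (levels - 1)
    return img, (msk > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def dice_ce_loss(
    logits: np.ndarray,
    truth: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
    eps: float = 1e-6,
    return_grad: bool = False,
):
    """Equal-weighted soft-Dice + cross-entropy segmentation loss.

    ``logits`` is ``(N, 2, H, W)`` (or ``(2, H, W)``), ``truth`` a binary
    mask of matching spatial shape.  The Dice term is ``1 - (2 S + eps) /
    (|P| + |T| + eps)`` computed on the softmax band-channel probability
    over all pixels; the cross-entropy term is the pixel-mean two-class
    cross-entropy.  Optionally also returns the analytic gradient with
    respect to the logits.
    """
    single = logits.ndim == 3
    if single:
        logits = logits[None]
        truth = np.asarray(truth)[None]
    truth = (np.asarray(truth) > 0).astype(np.float64)
    if logits.shape[0] != truth.shape[0] or logits.shape[2:] != truth.shape[1:]:
        raise ValueError(f"shape mismatch: logits {logits.shape}, truth {truth.shape}")
    w_dice, w_ce = weights
    p = _softmax2(logits.astype(np.float64))
    p1 = p[:, 1]
    npix = truth.size

    s = float((p1 * truth).sum())
    a = float(p1.sum())
    b = float(truth.sum())
    dice = (2 * s + eps) / (a + b + eps)
    dice_term = 1.0 - dice

    p_true = np.where(truth > 0, p1, p[:, 0])
    ce_term = float(-np.log(np.maximum(p_true, 1e-12)).mean())

    loss = w_dice * dice_term + w_ce * ce_term
    if not return_grad:
        return loss

    # gradient of the dice term wrt p1, then through the 2-class softmax
    dD_dp1 = (2 * truth * (a + b + eps) - (2 * s + eps)) / (a + b + eps) ** 2
    dL_dp1 = -w_dice * dD_dp1
    p0 = p[:, 0]
    grad = np.zeros_like(p)
    grad[:, 1] = dL_dp1 * p1 * (1 - p1)
    grad[:, 0] = dL_dp1 * (-p1 * p0)
    # cross-entropy gradient: (softmax - onehot) / npix
    onehot = np.stack([1 - truth, truth], axis=1)
    grad += w_ce * (p - onehot) / npix
    if single:
        grad = grad[0]
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_dataset(
    items: list,
    sources: list | None = None,
    fracs: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Per-source shuffled train/validation/test split.

    Each source is shuffled and split with largest-remainder rounding so
    every source is represented in every subset; the per-source splits are
    then concatenated.  A source with fewer than 3 items goes wholly to the
    training set with a warning.  Deterministic under ``seed``.
    """
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if sources is None:
        sources = ["default"] * len(items)
    if len(sources) != len(items):
        raise ValueError("sources must parallel items")
    rng = np.random.default_rng(seed)
    by_source: dict = {}
    for item, src in zip(items, sources):
        by_source.setdefault(src, []).append(item)

    train: list = []
    val: list = []
    test: list = []
    for src in sorted(by_source, key=str):
        group = by_source[src]
        n = len(group)
        if n < 3:
            warnings.warn(f"source {src!r} has fewer than 3 items; assigning all to train")
            train.extend(group)
            continue
        order = rng.permutation(n)
        exact = np.array(fracs) * n
        counts = np.floor(exact).astype(int)
        remainder = n - counts.sum()
        for idx in np.argsort(-(exact - counts))[:remainder]:
            counts[idx] += 1
        a, b_count, _ = counts
        idx_train = order[:a]
        idx_val = order[a : a + b_count]
        idx_test = order[a + b_count :]
        train.extend(group[i] for i in idx_train)
        val.extend(group[i] for i in idx_val)
        test.extend(group[i] for i in idx_test)
    return train, val, test


def _item_to_arrays(item) -> tuple[np.ndarray, np.ndarray]:
    """Convert a dataset item to (normalised image, binary mask)."""
    image, mask = item
    if isinstance(image, GelImage):
        img01 = normalize01(image)
    else:
        img01 = np.asarray(image, dtype=np.float64)
        if img01.max(initial=0.0) > 1.0:
            raise ValueError("raw arrays must be pre-normalised to [0, 1]")
    classes = mask.classes if isinstance(mask, SegmentationMask) else np.asarray(mask)
    return img01, (classes > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _batch_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = float(np.logical_and(pred > 0, truth > 0).sum())
    denom = float((pred > 0).sum() + (truth > 0).sum())
    return 1.0 if denom == 0 else 2 * inter / denom


def train(
    dataset: dict,
    config: TrainingConfig,
    model: UNet | None = None,
    restricted_augment: bool = False,
) -> tuple[dict, list[dict]]:
    """Train the segmentation network.

    ``dataset`` maps ``'train'``/``'val'`` to lists of ``(image, mask)``
    pairs (GelImage or pre-normalised arrays).  Optimises the combined
    soft-Dice/cross-entropy loss with Adam under the cosine warm-restart
    schedule; the validation Dice is computed every epoch on un-augmented,
    crop-backed predictions; the returned checkpoint is the epoch with the
    highest validation Dice.

    Returns ``(checkpoint, log)`` where ``checkpoint`` carries the model
    state and metadata and ``log`` has one record per epoch: ``epoch``,
    ``train_loss``, ``val_dice``, ``lr``.
    """
    train_items = dataset.get("train") or []
    val_items = dataset.get("val") or []
    if not train_items or not val_items:
        raise ValueError("both train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_model(width_multiplier=config.width_multiplier, seed=config.seed)
    params = model.parameters()
    optimiser = Adam(params, lr=config.lr_init)

    train_arrays = [_item_to_arrays(it) for it in train_items]
    val_arrays = [_item_to_arrays(it) for it in val_items]
    global_target = None
    if config.global_pad:
        global_target = max(max(a.shape) for a, _ in train_arrays + val_arrays)

    best_state = model.get_state()
    best_val = -np.inf
    best_epoch = -1
    log: list[dict] = []
    for epoch in range(config.max_epochs):
        lr = cosine_warm_restart_lr(epoch, config.lr_init, config.lr_min, config.restart_period)
        optimiser.lr = lr
        order = rng.permutation(len(train_arrays))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            imgs, msks, pad_records = [], [], []
            for bi in batch_idx:
                img01, msk = train_arrays[bi]
                img01, msk = augment(img01, msk, rng, config.augment_probs,
                                     restricted=restricted_augment)
                imgs.append(img01)
                msks.append(msk)
            # pad every batch item to the batch max (or the global max)
            target = global_target
            if target is None:
                target = max(max(a.shape) for a in imgs)
            x = []
            t = []
            for img01, msk in zip(imgs, msks):
                pi, pads = _pad_to_square_multiple(img01, config.pad_multiple, target)
                pm, _ = _pad_to_square_multiple(msk.astype(float), config.pad_multiple, target)
                x.append(pi)
                t.append(pm > 0)
            x = np.stack(x)[:, None].astype(np.float32)
            t = np.stack(t)
            logits = model.forward(x, train=True)
            loss, grad = dice_ce_loss(logits, t, config.loss_weights, return_grad=True)
            optimiser.zero_grad()
            model.backward(grad)
            optimiser.step()
            epoch_losses.append(loss)

        val_scores = []
        for img01, msk in val_arrays:
            pred = _predict_from_array(model, img01, config.pad_multiple)
            val_scores.append(_batch_dice(pred, msk))
        val_dice = float(np.mean(val_scores))
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_dice": val_dice,
                "lr": float(lr),
            }
        )
        if val_dice > best_val:
            best_val = val_dice
            best_epoch = epoch
            best_state = model.get_state()

    model.set_state(best_state)
    checkpoint = {
        "state": best_state,
        "epoch": best_epoch,
        "val_dice": best_val,
        "config": asdict(config),
        "arch": {
            "in_channels": model.in_channels,
            "out_channels": model.out_channels,
            "width_multiplier": model.width_multiplier,
            "seed": model.seed,
        },
    }
    return checkpoint, log


def fine_tune(
    model: UNet,
    new_dataset: dict | list,
    epochs: int = 11,
    config: TrainingConfig | None = None,
) -> tuple[dict, list[dict]]:
    """Continue training an existing model on a new dataset.

    Same loop as :func:`train` but augmentation is restricted to flips and
    rotations and the epoch budget defaults to 11.  ``new_dataset`` may be a
    plain list of ``(image, mask)`` pairs, in which case it is used for both
    training and (un-augmented) validation and the last epoch is returned;
    with an explicit ``val`` split the best-validation epoch is returned.
    """
    if config is None:
        config = TrainingConfig(width_multiplier=model.width_multiplier)
    if isinstance(new_dataset, list):
        if not new_dataset:
            raise ValueError("fine-tuning dataset is empty")
        dataset = {"train": new_dataset, "val": new_dataset}
    else:
        dataset = new_dataset
        if not dataset.get("train"):
            raise ValueError("fine-tuning dataset is empty")
    cfg = copy.deepcopy(config)
    cfg.max_epochs = epochs
    if epochs == 0:
        checkpoint = {
            "state": model.get_state(),
            "epoch": -1,
            "val_dice": float("nan"),
            "config": asdict(cfg),
            "arch": {
                "in_channels": model.in_channels,
                "out_channels": model.out_channels,
                "width_multiplier": model.width_multiplier,
                "seed": model.seed,
            },
        }
        return checkpoint, []
    return train(dataset, cfg, model=model, restricted_augment=True)


def _predict_from_array(model: UNet, img01: np.ndarray, pad_multiple: int = 32) -> np.ndarray:
    padded, pads = _pad_to_square_multiple(img01, pad_multiple)
    logits = model.forward(padded[None, None].astype(np.float32), train=False)[0]
    band = logits[1] > logits[0]  # ties resolve to background
    return crop_back(band, pads).astype(np.uint8)


def predict_mask(model: UNet, image: GelImage, pretreat: str = "raw") -> SegmentationMask:
    """Segment an image: normalise, pad, forward pass, per-pixel argmax, crop.

    Equal logits resolve to background.  Output shape always equals the
    input shape.
    """
    if pretreat == "raw":
        img01 = normalize01(image)
    elif pretreat == "percentile":
        img01 = percentile_normalize(image)
    else:
        raise ValueError(f"unknown pretreat {pretreat!r}")
    return SegmentationMask(_predict_from_array(model, img01))


# ---------------------------------------------------------------------------
# checkpoint files
# ---------------------------------------------------------------------------

def save_checkpoint(checkpoint: dict, path: str | Path) -> None:
    """Write a checkpoint as .npz with a JSON metadata sidecar."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(checkpoint["state"])}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    """Restore a model (and metadata) written by :func:`save_checkpoint`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npz"))
    state = [data[f"arr_{i}"] for i in range(len(data.files))]
    arch = meta["arch"]
    model = build_model(
        arch["in_channels"], arch["out_channels"], arch["width_multiplier"], arch["seed"]
    )
    model.set_state(state)
    meta["state"] = state
    return model, meta


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------

class UNetSegmenter(BaseEstimator):
    """Scikit-learn-style wrapper around the trainable segmenter.

    ``fit(X, y)`` takes parallel lists of images (GelImage or normalised
    arrays) and masks, carves a validation subset per ``split_fracs`` (the
    test fraction is returned to the caller's control — fit only uses train
    and val), trains, and keeps the best-validation-Dice checkpoint.
    """

    def __init__(
        self,
        width_multiplier: float = 1.0,
        max_epochs: int = 600,
        batch_size: int = 2,
        lr_init: float = 1e-4,
        lr_min: float = 1e-7,
        restart_period: int = 100,
        pad_multiple: int = 32,
        seed: int = 0,
        pretreat: str = "raw",
    ):
        self.width_multiplier = width_multiplier
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.lr_min = lr_min
        self.restart_period = restart_period
        self.pad_multiple = pad_multiple
        self.seed = seed
        self.pretreat = pretreat

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            lr_init=self.lr_init,
            lr_min=self.lr_min,
            restart_period=self.restart_period,
            pad_multiple=self.pad_multiple,
            seed=self.seed,
            width_multiplier=self.width_multiplier,
        )

    def fit(self, X, y):  # noqa: N803 - sklearn signature
        items = list(zip(X, y))
        if len(items) < 2:
            raise ValueError("need at least two image/mask pairs (train + val)")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(items))
        n_val = max(1, int(round(0.1 * len(items))))
        val = [items[i] for i in order[:n_val]]
        tr = [items[i] for i in order[n_val:]]
        config = self._config()
        checkpoint, log = train({"train": tr, "val": val}, config)
        self.model_ = build_model(width_multiplier=self.width_multiplier, seed=self.seed)
        self.model_.set_state(checkpoint["state"])
        self.checkpoint_ = checkpoint
        self.history_ = log
        self.best_epoch_ = checkpoint["epoch"]
        self.best_val_dice_ = checkpoint["val_dice"]
        return self

    def predict(self, image: GelImage | np.ndarray) -> SegmentationMask:
        if not hasattr(self, "model_"):
            raise AttributeError("UNetSegmenter is not fitted yet")
        if not isinstance(image, GelImage):
            image = GelImage(image, 16 if np.asarray(image).dtype == np.uint16 else 8)
        return predict_mask(self.model_, image, pretreat=self.pretreat)

    def score(self, X, y) -> float:  # noqa: N803
        """Mean Dice over a set of image/mask pairs."""
        from gelband.evaluation import dice_score

        scores = [dice_score(self.predict(img), msk) for img, msk in zip(X, y)]
        return float(np.mean(scores))
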