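"""Pupil segmentation: preprocessing, augmentation, a 2D U-Net, evaluation.

Frames from the two-eye recorder are split into eye halves, resampled to
320x240 grayscale in [0, 1], and segmented by an encoder-decoder U-Net with
skip connections and a per-pixel sigmoid head. Training follows the recipe
of learning rate 1e-4, 200 epochs, batch size 16, with the minimum
validation-loss weights kept ("best model"). Each training sample
contributes exactly three augmented variants: a horizontal mirror, a random
rotation within +/-15 degrees, and a random horizontal shift within +/-5%
of the image width — image and mask always transformed identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform
from skimage.util import img_as_float

from . import nn

__all__ = [
    "SegConfig", "UNet2D",
    "split_eyes", "preprocess", "augment",
    "hflip_pair", "rotate_pair", "shift_pair",
    "build_unet", "unet_param_count", "train_segmenter", "segment",
    "eval_segmentation", "save_segmenter", "load_segmenter",
]


@dataclass
class SegConfig:
    """U-Net shape and training hyperparameters.

    ``input_size`` is (width, height); both must be divisible by
    ``2 ** depth`` so the pooling pyramid closes. The default 320x240 at
    depth 4 matches the preprocessed eye images; the reduced ``test
    profile`` (depth 3, base_filters 8, smaller input) exists for CPU runs.
    """

    depth: int = 4
    base_filters: int = 16
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 16
    mask_threshold: float = 0.5
    input_size: tuple[int, int] = (320, 240)

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        w, h = self.input_size
        div = 2 ** self.depth
        if w % div or h % div:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^depth={div}")

    @classmethod
    def test_profile(cls, input_size=(96, 72), epochs=20) -> "SegConfig":
        return cls(depth=3, base_filters=8, epochs=epochs, batch_size=8,
                   learning_rate=1e-3, input_size=input_size)


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------

def split_eyes(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a two-eye frame into (left, right) halves by column.

    The left eye occupies columns [0, W/2), the right eye [W/2, W); the
    partition is lossless (stacking the halves side by side reproduces the
    frame exactly).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a 2D grayscale frame")
    w = frame.shape[1]
    if w % 2:
        raise ValueError("frame width must be even")
    return frame[:, : w // 2].copy(), frame[:, w // 2:].copy()


def preprocess(image: np.ndarray, size: tuple[int, int] = (320, 240),
               is_mask: bool = False) -> np.ndarray:
    """Resample to ``size`` (width, height) grayscale with values in [0, 1].

    Images are resampled bilinearly; masks use nearest-neighbour so they
    stay strictly binary. 3-channel input is averaged to one channel
    (infrared frames carry no chroma).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        image = image.mean(axis=2)
    elif image.ndim != 2:
        raise ValueError(f"expected 2D or 3-channel image, got {image.shape}")
    image = img_as_float(image)
    w, h = size
    order = 0 if is_mask else 1
    out = sktransform.resize(image, (h, w), order=order,
                             anti_aliasing=False, preserve_range=True)
    if is_mask:
        return (out > 0.5).astype(np.float32)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def hflip_pair(image: np.ndarray, mask: np.ndarray):
    return image[:, ::-1].copy(), mask[:, ::-1].copy()


def rotate_pair(image: np.ndarray, mask: np.ndarray, angle: float):
    """Rotate image (bilinear) and mask (nearest) by the same angle."""
    img = sktransform.rotate(image, angle, order=1, mode="edge",
                             preserve_range=True)
    msk = sktransform.rotate(mask, angle, order=0, mode="constant", cval=0,
                             preserve_range=True)
    return img.astype(image.dtype), (msk > 0.5).astype(mask.dtype)


def shift_pair(image: np.ndarray, mask: np.ndarray, frac: float):
    """Shift image and mask horizontally by ``frac`` of the image width."""
    dx = frac * image.shape[1]
    img = ndimage.shift(image, (0, dx), order=1, mode="nearest")
    msk = ndimage.shift(mask, (0, dx), order=0, mode="constant", cval=0)
    return img.astype(image.dtype), msk.astype(mask.dtype)


def augment(image: np.ndarray, mask: np.ndarray, seed: int):
    """Produce exactly three augmented (image, mask) variants of a sample:
    horizontal mirror, random rotation in [-15, +15] degrees, and random
    horizontal shift in [-5%, +5%] of the width. The same geometric
    transform is always applied to image and mask.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-15.0, 15.0)
    frac = rng.uniform(-0.05, 0.05)
    return [hflip_pair(image, mask),
            rotate_pair(image, mask, angle),
            shift_pair(image, mask, frac)]


# ---------------------------------------------------------------------------
# the U-Net
# ---------------------------------------------------------------------------

class _Block:
    """A plain chain of layers with symmetric forward/backward."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params]

    def grads(self):
        return [g for l in self.layers for g in l.grads]


class UNet2D:
    """Encoder-decoder segmentation network with skip connections.

    Each encoder level applies two 3x3 convolutions (ReLU) and halves the
    resolution; the decoder mirrors it with nearest-neighbour upsampling,
    an up-convolution, concatenation of the matching encoder features, and
    two more convolutions. A 1x1 convolution produces per-pixel logits;
    :meth:`predict` applies the sigmoid. Filters double at each level from
    ``base_filters``.
    """

    def __init__(self, config: SegConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        d, f = config.depth, config.base_filters
        filters = [f * 2 ** i for i in range(d + 1)]
        self.enc: list[_Block] = []
        self.pools: list[nn.MaxPool2D] = []
        c_in = 1
        for i in range(d):
            self.enc.append(_Block([
                nn.Conv2D(c_in, filters[i], 3, rng, dtype), nn.ReLU(),
                nn.Conv2D(filters[i], filters[i], 3, rng, dtype), nn.ReLU(),
            ]))
            self.pools.append(nn.MaxPool2D(2))
            c_in = filters[i]
        self.bottleneck = _Block([
            nn.Conv2D(filters[d - 1], filters[d], 3, rng, dtype), nn.ReLU(),
            nn.Conv2D(filters[d], filters[d], 3, rng, dtype), nn.ReLU(),
        ])
        self.ups: list[nn.Upsample2D] = []
        self.upconvs: list[_Block] = []
        self.dec: list[_Block] = []
        for i in range(d - 1, -1, -1):
            self.ups.append(nn.Upsample2D(2))
            self.upconvs.append(_Block([
                nn.Conv2D(filters[i + 1], filters[i], 3, rng, dtype),
                nn.ReLU(),
            ]))
            self.dec.append(_Block([
                nn.Conv2D(2 * filters[i], filters[i], 3, rng, dtype),
                nn.ReLU(),
                nn.Conv2D(filters[i], filters[i], 3, rng, dtype), nn.ReLU(),
            ]))
        self.head = nn.Conv2D(filters[0], 1, 1, rng, dtype)
        self._filters = filters

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Per-pixel logits for a batch ``(N, H, W, 1)``."""
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        for up, upconv, dec, skip in zip(self.ups, self.upconvs, self.dec,
                                         reversed(skips)):
            h = up.forward(h, train)
            h = upconv.forward(h, train)
            h = np.concatenate([skip, h], axis=-1)
            h = dec.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads = []
        for up, upconv, dec in zip(reversed(self.ups), reversed(self.upconvs),
                                   reversed(self.dec)):
            grad = dec.backward(grad)
            c_skip = grad.shape[-1] // 2
            skip_grads.append(grad[..., :c_skip])
            grad = upconv.backward(grad[..., c_skip:])
            grad = up.backward(grad)
        grad = self.bottleneck.backward(grad)
        # skip_grads were collected shallowest-first; the encoder unwinds
        # deepest-first, so pair them in reverse
        for block, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(skip_grads)):
            grad = pool.backward(grad)
            grad = block.backward(grad + gskip)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel pupil probabilities in [0, 1]."""
        return nn.sigmoid(self.forward(x, train=False))

    # -- parameter plumbing --------------------------------------------------
    def parameters(self):
        blocks = (self.enc + [self.bottleneck] + self.upconvs + self.dec)
        out = [p for b in blocks for p in b.params()]
        return out + list(self.head.params)

    def gradients(self):
        blocks = (self.enc + [self.bottleneck] + self.upconvs + self.dec)
        out = [g for b in blocks for g in b.grads()]
        return out + list(self.head.grads)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w


def build_unet(config: SegConfig, seed: int = 0) -> UNet2D:
    """Construct a randomly initialised U-Net for the given configuration."""
    return UNet2D(config, seed=seed)


def unet_param_count(depth: int, base_filters: int, in_channels: int = 1) -> int:
    """Closed-form trainable-parameter count of :class:`UNet2D`.

    Every 3x3 convolution of c_in -> c_out contributes ``9*c_in*c_out +
    c_out`` parameters; the head is a 1x1 convolution to one channel.
    """
    f = [base_filters * 2 ** i for i in range(depth + 1)]

    def conv(cin, cout, k=3):
        return k * k * cin * cout + cout

    total = 0
    cin = in_channels
    for i in range(depth):
        total += conv(cin, f[i]) + conv(f[i], f[i])
        cin = f[i]
    total += conv(f[depth - 1], f[depth]) + conv(f[depth], f[depth])
    for i in range(depth - 1, -1, -1):
        total += conv(f[i + 1], f[i])                 # up-convolution
        total += conv(2 * f[i], f[i]) + conv(f[i], f[i])
    total += conv(f[0], 1, k=1)
    return total


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _as_batches(images: np.ndarray, masks: np.ndarray):
    x = np.asarray(images, dtype=np.float32)[..., None]
    y = np.asarray(masks, dtype=np.float32)[..., None]
    return x, y


def train_segmenter(train_samples, val_samples, config: SegConfig,
                    seed: int = 0):
    """Train the U-Net with per-pixel binary cross-entropy and Adam.

    Parameters
    ----------
    train_samples, val_samples : (images, masks) pairs of stacks shaped
        ``(N, H, W)`` with images in [0, 1] and masks in {0, 1}.
    config : shape and recipe (defaults: lr 1e-4, 200 epochs, batch 16).
    seed : controls weight initialisation and batch shuffling.

    Returns
    -------
    model : the U-Net carrying the minimum-validation-loss weights.
    history : dict with per-epoch ``train_loss`` and ``val_loss`` lists and
        the index of the selected epoch (``best_epoch``).
    """
    config.validate()
    xt, yt = _as_batches(*train_samples)
    xv, yv = _as_batches(*val_samples)
    if len(xt) == 0 or len(xv) == 0:
        raise ValueError("need at least one training and one validation sample")
    rng = np.random.default_rng(seed)
    model = UNet2D(config, seed=int(rng.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), model.gradients(),
                  lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(len(xt))
        losses = []
        for start in range(0, len(xt), bs):
            idx = order[start:start + bs]
            logits = model.forward(xt[idx], train=True)
            loss, grad = nn.bce_with_logits(logits, yt[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_losses = []
        for start in range(0, len(xv), bs):
            logits = model.forward(xv[start:start + bs], train=False)
            loss, _ = nn.bce_with_logits(logits, yv[start:start + bs])
            val_losses.append(loss * len(xv[start:start + bs]))
        val_loss = float(np.sum(val_losses) / len(xv))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, model.get_weights(), epoch)
    model.set_weights(best[1])
    history["best_epoch"] = best[2]
    return model, history


def segment(model: UNet2D, image: np.ndarray,
            mask_threshold: float | None = None) -> np.ndarray:
    """Binary pupil mask(s) for a preprocessed image or image stack."""
    if mask_threshold is None:
        mask_threshold = model.config.mask_threshold
    image = np.asarray(image, dtype=np.float32)
    single = image.ndim == 2
    if single:
        image = image[None]
    probs = model.predict(image[..., None])[..., 0]
    masks = probs > mask_threshold
    return masks[0] if single else masks


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_METRICS = ("sensitivity", "specificity", "precision", "accuracy", "dsc")


def eval_segmentation(pred_masks: np.ndarray, gt_masks: np.ndarray) -> dict:
    """Pixel-level confusion metrics per image, summarised as mean +/- sd.

    Returns a dict with ``per_image`` (metric -> array, percent) and
    ``mean`` / ``sd`` (metric -> float). A metric whose denominator is zero
    on some image (e.g. sensitivity on an all-background ground truth) is
    NaN there and excluded from the summary.
    """
    pred = np.asarray(pred_masks).astype(bool)
    gt = np.asarray(gt_masks).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground-truth stacks differ in shape")
    if pred.ndim == 2:
        pred, gt = pred[None], gt[None]
    axes = tuple(range(1, pred.ndim))
    tp = np.sum(pred & gt, axis=axes, dtype=float)
    fp = np.sum(pred & ~gt, axis=axes, dtype=float)
    fn = np.sum(~pred & gt, axis=axes, dtype=float)
    tn = np.sum(~pred & ~gt, axis=axes, dtype=float)

    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, np.nan)
        return 100.0 * out

    per_image = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "dsc": ratio(2 * tp, 2 * tp + fp + fn),
    }
    mean = {k: float(np.nanmean(v)) if np.any(np.isfinite(v)) else np.nan
            for k, v in per_image.items()}
    sd = {k: float(np.nanstd(v)) if np.any(np.isfinite(v)) else np.nan
          for k, v in per_image.items()}
    return {"per_image": per_image, "mean": mean, "sd": sd}


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_segmenter(path: str | Path, model: UNet2D) -> None:
    """Single-file checkpoint: config JSON + flat weight arrays (npz)."""
    cfg = asdict(model.config)
    cfg["input_size"] = list(cfg["input_size"])
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_segmenter(path: str | Path) -> UNet2D:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        cfg["input_size"] = tuple(cfg["input_size"])
        model = UNet2D(SegConfig(**cfg))
        weights = [data[f"w{i}"] for i in range(len(model.parameters()))]
    model.set_weights(weights)
    return model
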