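"""Training of the segmentation U-net on weak or curated labels.

Implements the preprocessing (per-image min-max normalisation), augmentation
(paired random reflection and 90-degree rotation), the generalized dice loss
for the strong class imbalance, the seeded train/validation/test split, and a
scikit-learn-style estimator (``UNetSegmenter``) running SGD with momentum,
L2 regularisation and a stepped learning-rate schedule.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import TrainConfig, UNetSpec
from .masks import N_CLASSES, validate_mask
from .nn.unet import UNet

EPS = 1e-7


# ---------------------------------------------------------------------------
# data handling


def split_dataset(sample_ids: list, fractions=(0.85, 0.10, 0.05), seed: int = 0):
    """Seeded shuffle, then floor-sized validation/test with remainder to train.

    Returns (train, val, test) id lists forming a partition of the input.
    """
    if not sample_ids:
        raise ValueError("cannot split an empty id list")
    if min(fractions) < 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample_ids))
    shuffled = [sample_ids[i] for i in order]
    n = len(shuffled)
    n_val = int(math.floor(n * fractions[1]))
    n_test = int(math.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def normalize(image: np.ndarray) -> np.ndarray:
    """Per-image, per-channel min-max scaling to [0, 1]; constant channel -> 0."""
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    out = np.zeros_like(image)
    for c in range(image.shape[-1]):
        ch = image[..., c]
        lo, hi = ch.min(), ch.max()
        if hi > lo:
            out[..., c] = (ch - lo) / (hi - lo)
    return out


def augment_pair(image: np.ndarray, mask: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Identical random reflection and 90-degree rotation on image and mask.

    ``rng`` may be a Generator or an integer seed.  Flips along each axis are
    drawn independently with probability 1/2; the rotation count is uniform
    over {0, 1, 2, 3} quarter-turns.  Pixel-permuting transforms only, so
    label masks need no interpolation.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask spatial shapes must match")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    flip_v = rng.uniform() < 0.5
    flip_h = rng.uniform() < 0.5
    k = int(rng.integers(0, 4))
    img, msk = image, mask
    if flip_v:
        img, msk = img[::-1], msk[::-1]
    if flip_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if k:
        img = np.rot90(img, k, axes=(0, 1))
        msk = np.rot90(msk, k, axes=(0, 1))
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# generalized dice loss


def _one_hot_nchw(masks: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((masks.shape[0], n_classes) + masks.shape[1:], dtype=np.float64)
    for c in range(n_classes):
        out[:, c] = masks == c
    return out


def generalized_dice_loss(scores: np.ndarray, truth: np.ndarray, return_grad: bool = False):
    """Generalized dice loss with squared inverse class-volume weights.

    ``scores``: per-pixel class probabilities, class axis first after an
    optional batch axis ((K, ...) or (N, K, ...)); ``truth``: one-hot of the
    same shape.  With r the reference and p the prediction,

        w_l = 1 / (sum_n r_ln + eps)^2
        loss = 1 - 2 * (sum_l w_l sum_n r_ln p_ln) /
                       (sum_l w_l sum_n (r_ln + p_ln) + eps)

    so rare classes count as much as abundant ones.  Loss is 0 for a perfect
    one-hot prediction and 1 when all mass sits on wrong classes.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if scores.shape != truth.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs truth {truth.shape}")
    # class axis: 1 if a batch axis is present (4-D), else 0
    class_axis = 1 if scores.ndim == 4 else 0
    sum_axes = tuple(i for i in range(scores.ndim) if i != class_axis)

    r_sum = truth.sum(axis=sum_axes)
    w = 1.0 / (r_sum + EPS) ** 2
    intersect = (truth * scores).sum(axis=sum_axes)
    totals = (truth + scores).sum(axis=sum_axes)
    num = 2.0 * (w * intersect).sum()
    den = (w * totals).sum() + EPS
    loss = 1.0 - num / den
    if not return_grad:
        return float(loss)
    # d loss / d p_ln = -2 (w_l r_ln den/?? ) ... derivative of 1 - num/den:
    #   -(dnum * den - num * dden) / den^2, dnum/dp_ln = 2 w_l r_ln, dden/dp_ln = w_l
    shape = [1] * scores.ndim
    shape[class_axis] = scores.shape[class_axis]
    w_b = w.reshape(shape)
    r = truth
    grad = -(2.0 * w_b * r * den - num * w_b) / den**2
    return float(loss), grad


# ---------------------------------------------------------------------------
# estimator


class UNetSegmenter(BaseEstimator):
    """U-net semantic segmenter trained with SGDM and generalized dice loss.

    Parameters mirror the training schedule: momentum 0.9, L2 0.001, initial
    learning rate 0.002 (weak-label regime; use 0.001 for the curated regime),
    dropped by ``lr_drop_factor`` every ``lr_drop_every`` epochs, mini-batches
    of 4.  ``fit`` expects lists of (H, W, in_channels) images and (H, W)
    label masks; images are min-max normalised per channel and pairs are
    augmented by random reflection/rotation each epoch.

    Fitted attributes: ``net_`` (the underlying network), ``training_log_``
    (per-epoch loss records), ``classes_``.
    """

    def __init__(
        self,
        depth: int = 3,
        base_filters: int = 16,
        n_classes: int = N_CLASSES,
        in_channels: int = 2,
        initial_lr: float = 0.002,
        momentum: float = 0.9,
        l2: float = 0.001,
        lr_drop_factor: float = 0.8,
        lr_drop_every: int = 3,
        batch_size: int = 4,
        epochs: int = 15,
        augment: bool = True,
        seed: int = 0,
    ):
        self.depth = depth
        self.base_filters = base_filters
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.initial_lr = initial_lr
        self.momentum = momentum
        self.l2 = l2
        self.lr_drop_factor = lr_drop_factor
        self.lr_drop_every = lr_drop_every
        self.batch_size = batch_size
        self.epochs = epochs
        self.augment = augment
        self.seed = seed

    # -- schedule ------------------------------------------------------------

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch: drops by the factor every block."""
        drops = (epoch - 1) // self.lr_drop_every
        return self.initial_lr * self.lr_drop_factor**drops

    def _spec(self) -> UNetSpec:
        return UNetSpec(
            depth=self.depth,
            base_filters=self.base_filters,
            n_classes=self.n_classes,
            in_channels=self.in_channels,
        )

    # -- data plumbing ---------------------------------------------------------

    def _to_nchw(self, images: list[np.ndarray]) -> np.ndarray:
        arr = np.stack([normalize(img) for img in images])
        return arr.transpose(0, 3, 1, 2)

    def _batch_loss(self, x: np.ndarray, masks: np.ndarray, train: bool) -> float:
        self.net_.set_training(train)
        probs = self.net_.forward(x)
        truth = _one_hot_nchw(masks, self.n_classes)
        if train:
            loss, grad = generalized_dice_loss(probs, truth, return_grad=True)
            self.net_.backward(grad)
        else:
            loss = generalized_dice_loss(probs, truth)
        return loss

    # -- estimator API ---------------------------------------------------------

    def fit(self, X: list[np.ndarray], y: list[np.ndarray], validation_data=None):
        """Train on (images, masks); optional (images, masks) validation pair."""
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be non-empty and of equal length")
        if len(X) < self.batch_size:
            raise ValueError(
                f"need at least batch_size={self.batch_size} training pairs, got {len(X)}"
            )
        TrainConfig(
            initial_lr=self.initial_lr,
            momentum=self.momentum,
            l2=self.l2,
            lr_drop_factor=self.lr_drop_factor,
            lr_drop_every=self.lr_drop_every,
            batch_size=self.batch_size,
            epochs=self.epochs,
            augment=self.augment,
            seed=self.seed,
        )
        masks = [validate_mask(m) for m in y]
        present = set()
        for m in masks:
            present |= set(np.unique(m).tolist())
        for c in range(self.n_classes):
            if c not in present:
                warnings.warn(f"class {c} absent from all training masks", stacklevel=2)

        self.classes_ = np.arange(self.n_classes)
        self.net_ = UNet(self._spec(), seed=self.seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xA06]))

        images_n = [normalize(img) for img in X]
        val = None
        if validation_data is not None:
            vx, vy = validation_data
            val = (self._to_nchw(vx), np.stack([validate_mask(m) for m in vy]))

        self.training_log_ = []
        n = len(images_n)
        for epoch in range(1, self.epochs + 1):
            lr = self.lr_at_epoch(epoch)
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                batch_imgs, batch_masks = [], []
                for i in idx:
                    img, msk = images_n[i], masks[i]
                    if self.augment:
                        img, msk = augment_pair(img, msk, rng)
                    batch_imgs.append(img)
                    batch_masks.append(msk)
                xb = np.stack(batch_imgs).transpose(0, 3, 1, 2)
                mb = np.stack(batch_masks)
                loss = self._batch_loss(xb, mb, train=True)
                self.net_.sgdm_step(lr, self.momentum, self.l2)
                epoch_losses.append(loss)
            record = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(epoch_losses))}
            if val is not None:
                record["val_loss"] = float(
                    np.mean(
                        [
                            self._batch_loss(val[0][i : i + self.batch_size], val[1][i : i + self.batch_size], train=False)
                            for i in range(0, len(val[0]), self.batch_size)
                        ]
                    )
                )
            self.training_log_.append(record)
        return self

    def predict_proba(self, X: list[np.ndarray]) -> list[np.ndarray]:
        """Per-pixel class probabilities, (n_classes, H, W) per image."""
        check_is_fitted(self, "net_")
        self.net_.set_training(False)
        out = []
        stride = 2**self.depth
        for img in X:
            if img.shape[-1] != self.in_channels:
                raise ValueError(f"expected {self.in_channels} channels, got {img.shape[-1]}")
            x = normalize(img).transpose(2, 0, 1)[None]
            h, w = x.shape[2:]
            ph = (-h) % stride
            pw = (-w) % stride
            if ph or pw:
                x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
            probs = self.net_.forward(x)[0]
            out.append(probs[:, :h, :w])
        return out

    def predict(self, X: list[np.ndarray]) -> list[np.ndarray]:
        """Per-pixel argmax label mask for each image."""
        return [p.argmax(axis=0).astype(np.uint8) for p in self.predict_proba(X)]

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "net_")
        path = Path(path)
        weights = self.net_.get_weights()
        meta = {"params": self.get_params(), "training_log": self.training_log_}
        np.savez(
            path,
            meta=json.dumps(meta),
            **{f"w{i}": w for i, w in enumerate(weights)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        data = np.load(Path(path), allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        est = cls(**meta["params"])
        est.classes_ = np.arange(est.n_classes)
        est.net_ = UNet(est._spec(), seed=est.seed)
        n = sum(1 for key in data.files if key.startswith("w"))
        est.net_.set_weights([data[f"w{i}"] for i in range(n)])
        est.training_log_ = meta["training_log"]
        return est


def train_model(images, masks, config: TrainConfig, spec: UNetSpec, validation_data=None) -> UNetSegmenter:
    """Functional wrapper: build a ``UNetSegmenter`` from configs and fit it."""
    est = UNetSegmenter(
        depth=spec.depth,
        base_filters=spec.base_filters,
        n_classes=spec.n_classes,
        in_channels=spec.in_channels,
        initial_lr=config.initial_lr,
        momentum=config.momentum,
        l2=config.l2,
        lr_drop_factor=config.lr_drop_factor,
        lr_drop_every=config.lr_drop_every,
        batch_size=config.batch_size,
        epochs=config.epochs,
        augment=config.augment,
        seed=config.seed,
    )
    return est.fit(images, masks, validation_data=validation_data)


def predict(model: UNetSegmenter, image: np.ndarray) -> np.ndarray:
    """Label mask for one image."""
    return model.predict([image])[0]
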