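"""Vertebra L1-L5 segmentation with a 2-D encoder-decoder network.

The segmenter is a plain U-Net: a contracting path of double-convolution
blocks with 2x2 max pooling, an expanding path with nearest-neighbour
upsampling and skip concatenation, and a final 1x1 convolution producing
per-pixel scores for six classes (background + L1..L5).  Training minimises
the mean of a soft-Dice loss and cross-entropy, on Z-score normalised
intensities, optionally with five-fold cross-validation and score-mean
ensembling of the fold models.  All configuration is explicit in
:class:`SegConfig` rather than auto-tuned.

Because the five vertebra labels are distinguished by craniocaudal order
rather than appearance, the network input can include normalised row/column
coordinate channels (``coord_features``), which makes the ordering directly
learnable by a small network.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "VertebraMask",
    "SegConfig",
    "CoverageReport",
    "UNet",
    "SegmenterModel",
    "train_segmenter",
    "segment_vertebrae",
    "dice",
    "check_roi_coverage",
]

N_CLASSES = 6  # background + L1..L5


@dataclass(frozen=True)
class VertebraMask:
    """Integer label map: 0 background, 1..5 = L1..L5."""

    labels: np.ndarray
    anterior_side: str = "left"
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"labels must be 2-D, got shape {labels.shape}")
        vals = np.unique(labels)
        if not np.isin(vals, np.arange(6)).all():
            raise ValueError(f"labels must be in 0..5, found {vals}")
        if self.anterior_side not in ("left", "right"):
            raise ValueError(f"anterior_side must be 'left' or 'right', got {self.anterior_side!r}")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class SegConfig:
    """Explicit segmentation training configuration.

    The desk-scale defaults train a depth-5 U-Net on whole 256x128 phantom
    images.  ``clinical_preset()`` returns a full-scale configuration for
    clinical radiographs (9 encoder levels, 1536x1024 patches, batch 2,
    five-fold cross-validation).
    """

    depth: int = 5
    base_channels: tuple[int, ...] = (8, 16, 32, 64, 64)
    patch_size: tuple[int, int] = (256, 128)  # rows, cols
    batch_size: int = 4
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (dice, cross-entropy)
    folds: int = 1
    epochs: int = 12
    optimizer: str = "adam"  # "adam" or "sgd"
    learning_rate: float = 0.003
    momentum: float = 0.9
    val_fraction: float = 0.2
    coord_features: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 3:
            raise ValueError(f"depth must be >= 3, got {self.depth}")
        if len(self.base_channels) != self.depth:
            raise ValueError(f"base_channels must list {self.depth} values, got {self.base_channels}")
        f = 2 ** (self.depth - 1)
        if self.patch_size[0] % f or self.patch_size[1] % f:
            raise ValueError(f"patch_size {self.patch_size} must be divisible by 2^(depth-1) = {f}")
        if self.folds < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("folds, epochs and batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")

    @classmethod
    def clinical_preset(cls) -> "SegConfig":
        return cls(
            depth=9,
            base_channels=(32, 64, 128, 256, 512, 512, 512, 512, 512),
            patch_size=(1536, 1024),
            batch_size=2,
            folds=5,
            epochs=1000,
        )

    @property
    def in_channels(self) -> int:
        return 3 if self.coord_features else 1


class _DoubleConv(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        self.seq = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, bias=False, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
        )

    def forward(self, x, train=False):
        return self.seq(x, train)

    def backward(self, gy):
        return self.seq.backward(gy)


class UNet(nn.Module):
    """Encoder-decoder segmentation network with skip connections."""

    def __init__(self, config: SegConfig, rng: np.random.Generator):
        ch = config.base_channels
        d = config.depth
        self.depth = d
        self.enc = [_DoubleConv(config.in_channels if i == 0 else ch[i - 1], ch[i], rng) for i in range(d)]
        self.pools = [nn.MaxPool2d() for _ in range(d - 1)]
        self.ups = [nn.UpsampleNearest2d() for _ in range(d - 1)]
        self.dec = [_DoubleConv(ch[i + 1] + ch[i], ch[i], rng) for i in range(d - 1)]
        self.head = nn.Conv2d(ch[0], N_CLASSES, 1, rng=rng)

    def forward(self, x, train=False):
        skips = []
        for i in range(self.depth - 1):
            x = self.enc[i](x, train)
            skips.append(x)
            x = self.pools[i](x, train)
        x = self.enc[-1](x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for i in range(self.depth - 2, -1, -1):
            x = self.ups[i](x, train)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i](x, train)
        return self.head(x, train)

    def backward(self, gy):
        gy = self.head.backward(gy)
        gskips = [None] * (self.depth - 1)
        for i in range(self.depth - 1):
            gy = self.dec[i].backward(gy)
            c = self._skip_channels[i]
            gskips[i] = gy[:, :c]
            gy = self.ups[i].backward(gy[:, c:])
        gy = self.enc[-1].backward(gy)
        for i in range(self.depth - 2, -1, -1):
            gy = self.pools[i].backward(gy)
            gy = gy + gskips[i]
            gy = self.enc[i].backward(gy)
        return gy


def _zscore(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    sd = image.std()
    if sd == 0:
        return np.zeros_like(image)
    return (image - image.mean()) / sd


def _to_input(image: np.ndarray, coord_features: bool) -> np.ndarray:
    """Z-scored intensity (+ optional normalised coordinate channels), (C,H,W)."""
    z = _zscore(image)
    if not coord_features:
        return z[None]
    H, W = z.shape
    rr = np.linspace(-1, 1, H, dtype=np.float32)[:, None] * np.ones((1, W), dtype=np.float32)
    cc = np.ones((H, 1), dtype=np.float32) * np.linspace(-1, 1, W, dtype=np.float32)[None]
    return np.stack([z, rr, cc])


@dataclass
class SegmenterModel:
    """Trained segmenter: one U-Net per fold, plus its configuration."""

    nets: list[UNet]
    config: SegConfig
    history: list[dict] = field(default_factory=list)

    def scores(self, image: np.ndarray) -> np.ndarray:
        """Fold-averaged class probability maps, (n_classes, H, W)."""
        x = _to_input(np.asarray(image, dtype=np.float32), self.config.coord_features)[None]
        acc = None
        for net in self.nets:
            p = nn.softmax(net(x, train=False), axis=1)[0]
            acc = p if acc is None else acc + p
        return acc / len(self.nets)


def train_segmenter(train, config: SegConfig = SegConfig()) -> SegmenterModel:
    """Train the vertebra segmenter on labelled samples.

    Parameters
    ----------
    train
        Sequence of objects with ``image`` (2-D float array) and
        ``vertebra_mask`` attributes (e.g. :class:`~aacscore.phantom.PhantomSample`),
        or ``(image, labels)`` pairs.
    config
        Training configuration; ``folds > 1`` trains one network per
        cross-validation fold and ensembles them by score averaging.

    The loss is the configured mix of soft-Dice and cross-entropy; the
    optimiser is Adam by default (SGD with momentum selectable), both under
    a polynomial learning-rate decay ``lr * (1 - t/T)^0.9``.
    """
    config.validate()
    pairs = []
    for item in train:
        if hasattr(item, "vertebra_mask"):
            pairs.append((np.asarray(item.image, np.float32), np.asarray(item.vertebra_mask.labels)))
        else:
            image, labels = item
            labels = np.asarray(getattr(labels, "labels", labels))
            pairs.append((np.asarray(image, np.float32), labels))
    if len(pairs) < 2 * config.folds:
        raise ValueError(f"need at least {2 * config.folds} training samples, got {len(pairs)}")
    for image, labels in pairs:
        if image.shape != labels.shape:
            raise ValueError("image and mask shapes differ")
        VertebraMask(labels=labels)  # structural validation

    X = np.stack([_to_input(im, config.coord_features) for im, _ in pairs]).astype(np.float32)
    Y = np.stack([lab for _, lab in pairs]).astype(np.int64)
    n = len(pairs)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)

    if config.folds == 1:
        n_val = max(1, int(round(config.val_fraction * n)))
        splits = [(order[n_val:], order[:n_val])]
    else:
        fold_idx = np.array_split(order, config.folds)
        splits = [
            (np.concatenate([fold_idx[j] for j in range(config.folds) if j != i]), fold_idx[i])
            for i in range(config.folds)
        ]

    w_dice, w_ce = config.loss_weights
    # inverse-frequency CE class weights (tempered by sqrt), mean-normalised;
    # keeps minority vertebra labels from collapsing into background early on
    counts = np.bincount(Y.ravel(), minlength=N_CLASSES).astype(np.float64)
    cw = np.sqrt(counts.sum() / (N_CLASSES * np.maximum(counts, 1.0)))
    cw = (cw / cw.mean()).astype(np.float32)
    nets, history = [], []
    for fold, (tr_idx, va_idx) in enumerate(splits):
        net = UNet(config, rng=np.random.default_rng(config.seed + 1000 + fold))
        if config.optimizer == "adam":
            opt = nn.Adam(net.parameters(), lr=config.learning_rate)
        else:
            opt = nn.SGD(net.parameters(), lr=config.learning_rate, momentum=config.momentum)
        n_batches = int(np.ceil(len(tr_idx) / config.batch_size))
        total_steps = config.epochs * n_batches
        step = 0
        for epoch in range(config.epochs):
            perm = rng.permutation(tr_idx)
            ep_loss = 0.0
            for b in range(n_batches):
                idx = perm[b * config.batch_size : (b + 1) * config.batch_size]
                opt.lr = config.learning_rate * (1 - step / total_steps) ** 0.9
                opt.zero_grad()
                logits = net(X[idx], train=True)
                loss, gz = nn.dice_ce_loss(logits, Y[idx], N_CLASSES, w_dice=w_dice, w_ce=w_ce,
                                           class_weights=cw)
                net.backward(gz)
                opt.step()
                ep_loss += loss
                step += 1
            val_dice = _mean_foreground_dice(net, X[va_idx], Y[va_idx])
            history.append(
                {"fold": fold, "epoch": epoch, "train_loss": ep_loss / n_batches,
                 "val_dice": val_dice, "lr": opt.lr, "time": time.time()}
            )
        nets.append(net)
    return SegmenterModel(nets=nets, config=config, history=history)


def _mean_foreground_dice(net: UNet, X: np.ndarray, Y: np.ndarray) -> float:
    dices = []
    for i in range(len(X)):
        pred = net(X[i : i + 1], train=False)[0].argmax(axis=0)
        for lab in range(1, N_CLASSES):
            if (Y[i] == lab).any():
                dices.append(dice(pred == lab, Y[i] == lab))
    return float(np.mean(dices)) if dices else float("nan")


def segment_vertebrae(model: SegmenterModel, image: np.ndarray, anterior_side: str = "left") -> VertebraMask:
    """Predict the vertebra label mask for one image.

    Post-processing keeps, for each label, only its largest connected
    component, so the output always satisfies one-component-per-label.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    labels = model.scores(image).argmax(axis=0).astype(np.uint8)
    labels = _largest_components(labels)
    return VertebraMask(labels=labels, anterior_side=anterior_side)


def _largest_components(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    for lab in range(1, N_CLASSES):
        mask = labels == lab
        if not mask.any():
            continue
        comp, n = ndimage.label(mask)
        if n == 1:
            out[mask] = lab
        else:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            out[comp == (int(np.argmax(sizes)) + 1)] = lab
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass(frozen=True)
class CoverageReport:
    """Result of the ROI-coverage quality check on a predicted mask."""

    passed: bool
    reasons: tuple[str, ...] = ()


def check_roi_coverage(
    mask: VertebraMask, height_ratio_bounds: tuple[float, float] = (0.3, 3.0)
) -> CoverageReport:
    """Check that a mask is usable for anatomical ROI extraction.

    Criteria (configurable): all five labels present, exactly one connected
    component each, superior-to-inferior ordering, and each vertebra height
    within ``height_ratio_bounds`` times the median of the five heights.
    """
    labels = mask.labels
    reasons: list[str] = []
    extents = {}
    for lab in range(1, N_CLASSES):
        m = labels == lab
        if not m.any():
            reasons.append(f"missing L{lab}")
            continue
        _, n = ndimage.label(m)
        if n != 1:
            reasons.append(f"L{lab} split into {n} components")
        rows = np.flatnonzero(m.any(axis=1))
        extents[lab] = (int(rows[0]), int(rows[-1]) + 1)
    if len(extents) == 5:
        order = sorted(extents, key=lambda lab: extents[lab][0])
        if order != [1, 2, 3, 4, 5]:
            reasons.append(f"vertebrae out of order: {order}")
        heights = np.array([extents[lab][1] - extents[lab][0] for lab in range(1, 6)], dtype=float)
        med = float(np.median(heights))
        lo, hi = height_ratio_bounds
        for lab, h in zip(range(1, 6), heights):
            if not (lo * med <= h <= hi * med):
                reasons.append(f"L{lab} height {int(h)} outside [{lo}, {hi}] x median {med:.0f}")
    return CoverageReport(passed=not reasons, reasons=tuple(reasons))
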