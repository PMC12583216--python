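"""AAC score regression: residual CNN with SCse attention on ROI patches.

The regressor maps a normalised spine/aorta patch to a continuous AAC-24
score.  The backbone is a residual network (desk-scale default: one basic
block per stage with channels 8/16/32/64 on 125x250 inputs; the full-scale
preset mirrors a 34-layer layout with channels 64/128/256/512 on 500x1000
inputs) with a concurrent spatial-and-channel squeeze-and-excitation block
after each residual block, and a regression head of batch normalisation,
dropout (p = 0.5) and a single-output linear layer.

Training uses SGD (momentum 0.9, weight decay 5e-4) under a linear-warmup +
cosine-annealing schedule — the learning rate rises linearly from one third
of the base rate (0.0033) to the base 0.01 over the first 200 iterations,
then decays along a cosine to a floor of 1e-4 — minimising mean squared
error with validation-based early stopping (validation loss monitored every
10 epochs by default).  The training set is re-augmented before each epoch
with random brightness/contrast/noise/shift/scale/rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nn
from .kauppila import Severity, classify_severity
from .roi import Patch

__all__ = [
    "RegressorConfig",
    "TrainConfig",
    "AugmentConfig",
    "CNNRegressor",
    "build_regressor",
    "augment",
    "lr_at",
    "train_regressor",
    "predict_score",
    "predict_score_clamped",
    "predict_category",
]


@dataclass(frozen=True)
class RegressorConfig:
    """Backbone layout and head settings for the score regressor."""

    blocks_per_stage: tuple[int, ...] = (1, 1, 1, 1)
    stage_channels: tuple[int, ...] = (8, 16, 32, 64)
    stem_channels: int = 8
    attention: bool = True
    dropout: float = 0.5
    input_size: tuple[int, int] = (125, 250)  # (cols, rows)
    seed: int = 0

    def validate(self) -> None:
        if len(self.blocks_per_stage) != len(self.stage_channels):
            raise ValueError("blocks_per_stage and stage_channels must have equal length")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        # stem downsamples by 4, each stage after the first by 2
        total_stride = 4 * 2 ** (len(self.stage_channels) - 1)
        cols, rows = self.input_size
        if cols < total_stride or rows < total_stride:
            raise ValueError(
                f"input_size {self.input_size} too small for backbone striding (total stride {total_stride})"
            )

    @classmethod
    def clinical_preset(cls) -> "RegressorConfig":
        return cls(blocks_per_stage=(3, 4, 6, 3), stage_channels=(64, 128, 256, 512),
                   stem_channels=64, input_size=(500, 1000))


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser, schedule and stopping settings for regressor training."""

    base_lr: float = 0.01
    min_lr: float = 0.0001
    warmup_iters: int = 200
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 32
    max_epochs: int = 500
    val_check_every: int = 10
    patience: int = 3  # consecutive validation checks without improvement
    seed: int = 0

    @property
    def warmup_start_lr(self) -> float:
        return self.base_lr / 3.0

    def validate(self) -> None:
        if not 0 < self.min_lr < self.base_lr:
            raise ValueError("need 0 < min_lr < base_lr")
        if self.warmup_iters < 0:
            raise ValueError("warmup_iters must be >= 0")

    @classmethod
    def desk_preset(cls) -> "TrainConfig":
        return cls(batch_size=16, max_epochs=30, val_check_every=5, patience=4)


@dataclass(frozen=True)
class AugmentConfig:
    """Per-epoch random augmentation magnitudes.

    ``noise_sigma`` is expressed in grey levels of an ``intensity_scale``-
    level display range (default 255, i.e. 8-bit units) and is converted to
    the patch's own intensity range when applied, so the same configuration
    is meaningful for raw and Z-scored inputs.
    """

    brightness: float = 0.10          # additive, fraction of intensity range
    contrast: float = 0.10            # multiplicative about the mean
    noise_sigma: tuple[float, float] = (0.0, 10.0)
    intensity_scale: float = 255.0
    shift: float = 0.05               # fraction of image size
    scale: float = 0.05
    rotation: float = 30.0            # degrees

    def validate(self) -> None:
        for name in ("brightness", "contrast", "shift", "scale", "rotation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sigma[0] < 0 or self.noise_sigma[1] < self.noise_sigma[0]:
            raise ValueError("noise_sigma must be a non-negative (low, high) range")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(brightness=0, contrast=0, noise_sigma=(0.0, 0.0), shift=0, scale=0, rotation=0)


def augment(patch, config: AugmentConfig, seed: int):
    """Randomly augment a patch; the associated score label never changes.

    Applies, in fixed order: brightness, contrast, Gaussian noise, shift,
    scale, rotation — each sampled independently within the configured
    magnitudes.  Dimensions are preserved (shift/scale/rotation pad with
    zeros); all magnitudes zero returns the input unchanged.
    """
    config.validate()
    is_patch = isinstance(patch, Patch)
    a = np.array(patch.pixels if is_patch else patch, dtype=np.float32, copy=True)
    rng = np.random.default_rng(seed)
    rng_range = float(a.max() - a.min()) or 1.0

    if config.brightness > 0:
        a = a + rng.uniform(-config.brightness, config.brightness) * rng_range
    if config.contrast > 0:
        m = a.mean()
        a = m + (a - m) * (1.0 + rng.uniform(-config.contrast, config.contrast))
    if config.noise_sigma[1] > 0:
        sigma = rng.uniform(*config.noise_sigma) / config.intensity_scale * rng_range
        a = a + rng.normal(0.0, sigma, size=a.shape).astype(np.float32)
    if config.shift > 0:
        dr = rng.uniform(-config.shift, config.shift) * a.shape[0]
        dc = rng.uniform(-config.shift, config.shift) * a.shape[1]
        a = ndimage.shift(a, (dr, dc), order=1, mode="constant", cval=0.0)
    if config.scale > 0:
        z = 1.0 + rng.uniform(-config.scale, config.scale)
        center = (np.asarray(a.shape) - 1) / 2.0
        a = ndimage.affine_transform(
            a, np.diag([1.0 / z, 1.0 / z]), offset=center - center / z,
            order=1, mode="constant", cval=0.0,
        )
    if config.rotation > 0:
        angle = rng.uniform(-config.rotation, config.rotation)
        a = ndimage.rotate(a, angle, reshape=False, order=1, mode="constant", cval=0.0)

    a = a.astype(np.float32)
    if is_patch:
        return Patch(pixels=a, normalization=dict(patch.normalization), provenance=dict(patch.provenance))
    return a


def lr_at(iteration: int, total_iterations: int, config: TrainConfig) -> float:
    """Learning rate at a global iteration under warmup + cosine annealing.

    Linear from ``base_lr/3`` to ``base_lr`` over the first ``warmup_iters``
    iterations, then cosine decay to ``min_lr``, reaching the floor exactly
    at the final training step.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    w = config.warmup_iters
    if iteration < w:
        return config.warmup_start_lr + (config.base_lr - config.warmup_start_lr) * iteration / w
    span = max(1, total_iterations - 1 - w)
    t = min(1.0, (iteration - w) / span)
    return config.min_lr + 0.5 * (config.base_lr - config.min_lr) * (1.0 + math.cos(math.pi * t))


class CNNRegressor(nn.Module):
    """Residual backbone + SCse attention + regression head."""

    def __init__(self, config: RegressorConfig):
        config.validate()
        rng = np.random.default_rng(config.seed)
        self.config = config
        features: list[tuple[str, nn.Module]] = [
            ("stem_conv", nn.Conv2d(1, config.stem_channels, 7, stride=2, bias=False, rng=rng)),
            ("stem_bn", nn.BatchNorm2d(config.stem_channels)),
            ("stem_relu", nn.ReLU()),
            ("stem_pool", nn.MaxPool2d()),
        ]
        in_ch = config.stem_channels
        for s, (n_blocks, ch) in enumerate(zip(config.blocks_per_stage, config.stage_channels)):
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                features.append(
                    (f"layer{s + 1}_block{b + 1}",
                     nn.ResidualBlock(in_ch, ch, stride=stride, attention=config.attention, rng=rng))
                )
                in_ch = ch
        self.features = features
        self.gap = nn.GlobalAvgPool()
        self.head_bn = nn.BatchNorm1d(in_ch)
        self.head_dropout = nn.Dropout(config.dropout, seed=config.seed + 1)
        self.head_fc = nn.Linear(in_ch, 1, rng=rng)
        self._acts: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}

    # Module.parameters() walks __dict__; include the named feature list.
    def parameters(self):
        params = []
        for _, m in self.features:
            params.extend(m.parameters())
        for m in (self.head_bn, self.head_fc):
            params.extend(m.parameters())
        return params

    def _state_items(self):
        for name, m in self.features:
            yield name, m
        yield "gap", self.gap
        yield "head_bn", self.head_bn
        yield "head_fc", self.head_fc

    def layer_names(self) -> list[str]:
        return [name for name, _ in self.features]

    def forward(self, x, train=False):
        self._acts = {}
        for name, m in self.features:
            x = m(x, train)
            self._acts[name] = x
        f = self.head_dropout(self.head_bn(self.gap(x, train), train), train)
        return self.head_fc(f, train)[:, 0]

    def backward(self, gy):
        g = self.head_fc.backward(np.asarray(gy, dtype=np.float32).reshape(-1, 1))
        g = self.gap.backward(self.head_bn.backward(self.head_dropout.backward(g)))
        self._grads = {}
        for name, m in reversed(self.features):
            self._grads[name] = g
            g = m.backward(g)
        return g


def build_regressor(config: RegressorConfig = RegressorConfig()) -> CNNRegressor:
    """Build a seeded regressor; same seed gives identical initial weights."""
    return CNNRegressor(config)


def _as_array(patches) -> np.ndarray:
    """Stack patches/arrays into (N, 1, H, W) float32."""
    arrs = [np.asarray(p.pixels if isinstance(p, Patch) else p, dtype=np.float32) for p in patches]
    return np.stack(arrs)[:, None]


def train_regressor(
    train: tuple,
    val: tuple,
    rc: RegressorConfig = RegressorConfig(),
    tc: TrainConfig = TrainConfig(),
    augment_config: AugmentConfig | None = AugmentConfig(),
) -> tuple[CNNRegressor, list[dict]]:
    """Train the score regressor; returns ``(model, history)``.

    ``train`` and ``val`` are ``(patches, scores)`` pairs.  Augmentation
    (when configured) redraws the training set before each epoch; validation
    patches are never augmented.  Early stopping restores the parameters of
    the best validation checkpoint.
    """
    rc.validate()
    tc.validate()
    tr_patches, tr_scores = train
    va_patches, va_scores = val
    if len(tr_patches) == 0 or len(va_patches) == 0:
        raise ValueError("train and val splits must both be non-empty")
    tr_scores = np.asarray(tr_scores, dtype=np.float32)
    va_scores = np.asarray(va_scores, dtype=np.float32)
    if ((tr_scores < 0) | (tr_scores > 24)).any() or ((va_scores < 0) | (va_scores > 24)).any():
        raise ValueError("scores must lie in [0, 24]")

    X = _as_array(tr_patches)
    Xv = _as_array(va_patches)
    model = build_regressor(rc)
    opt = nn.SGD(model.parameters(), lr=tc.base_lr, momentum=tc.momentum, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)

    n = len(X)
    n_batches = int(np.ceil(n / tc.batch_size))
    total_iters = tc.max_epochs * n_batches
    history: list[dict] = []
    best_val, best_state, bad_checks = np.inf, None, 0
    it = 0
    for epoch in range(tc.max_epochs):
        if augment_config is not None:
            Xe = np.stack(
                [augment(X[i, 0], augment_config, seed=int(rng.integers(2**31 - 1))) for i in range(n)]
            )[:, None]
        else:
            Xe = X
        perm = rng.permutation(n)
        ep_loss = 0.0
        for b in range(n_batches):
            idx = perm[b * tc.batch_size : (b + 1) * tc.batch_size]
            opt.lr = lr_at(it, total_iters, tc)
            opt.zero_grad()
            pred = model(Xe[idx], train=True)
            loss, gp = nn.mse_loss(pred, tr_scores[idx])
            model.backward(gp)
            opt.step()
            history.append({"epoch": epoch, "iter": it, "lr": opt.lr, "train_mse": loss, "val_mse": np.nan})
            ep_loss += loss
            it += 1
        if (epoch + 1) % tc.val_check_every == 0 or epoch == tc.max_epochs - 1:
            val_mse = _eval_mse(model, Xv, va_scores, tc.batch_size)
            history[-1]["val_mse"] = val_mse
            if val_mse < best_val - 1e-6:
                best_val, best_state, bad_checks = val_mse, model.state(), 0
                best_state = {k: v.copy() for k, v in best_state.items()}
            else:
                bad_checks += 1
                if bad_checks >= tc.patience:
                    break
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def _eval_mse(model: CNNRegressor, X: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    preds = []
    for b in range(0, len(X), batch_size):
        preds.append(model(X[b : b + batch_size], train=False))
    preds = np.concatenate(preds)
    return float(np.mean((preds - y) ** 2))


def predict_score(model: CNNRegressor, patch) -> float:
    """Raw continuous score prediction for one patch."""
    x = _as_array([patch])
    cols, rows = model.config.input_size
    if x.shape[2:] != (rows, cols):
        raise ValueError(f"patch shape {x.shape[2:]} does not match model input (rows, cols)=({rows}, {cols})")
    return float(model(x, train=False)[0])


def predict_score_clamped(model: CNNRegressor, patch) -> float:
    """Score prediction clamped to the valid AAC-24 range [0, 24]."""
    return float(np.clip(predict_score(model, patch), 0.0, 24.0))


def predict_category(model: CNNRegressor, patch) -> Severity:
    """Severity category: clamp to [0, 24], round half-to-even, classify."""
    return classify_severity(int(np.round(predict_score_clamped(model, patch))))
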