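"""Conditional GAN mapping scalp segments X to intracranial estimates Ỹ = G(X).

The generator is a 1-D U-net over the time axis of a 64 x 12 segment: a
contracting path of kernel-5 convolutions, per-channel time normalization and
stride-2 average pooling (feature channels doubling per level), a bottleneck
convolution, and an expansive path of bilinear 2x upsampling, 1 x 1
feature-halving convolutions, skip concatenations, pairs of kernel-5
convolutions and time normalization, finished by a 1 x 1 convolution and a
time-distributed dense map to 12 output channels.

The discriminator scores the channel-wise concatenation of a scalp segment
with a (real or estimated) intracranial segment — a 64 x 24 input — through a
stack of kernel-5 convolutions with ReLU, dropout and stride-2 max pooling,
ending in a single sigmoid unit.

Training follows the min-max objective

    min_G max_D  L_GAN(G, D) = E[log D(X, Y)] + E[log(1 - D(X, G(X)))],

with the generator loss regularized by the expected Euclidean (Frobenius)
norm of the reconstruction error,  L_G = L_GAN + lambda * E[||Y - G(X)||_2].
The literal minimax generator update saturates early; by default the
non-saturating heuristic (maximize log D on fakes) is used, which shares the
same fixed points. Segments are standardized per channel with training-set
statistics; ``translate`` returns estimates back in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SegmentSet
from .errors import (ConfigurationError, InvalidInputError, InvalidParameterError,
                     ShapeError)
from .nn import (Adam, AvgPool1d, Conv1d, Dense, Dropout, MaxPool1d, Module,
                 Tensor, TimeNorm, concat, upsample_linear_2x)

__all__ = [
    "TranslatorConfig", "TrainedTranslator", "ChannelScaler", "UNetGenerator",
    "Discriminator", "build_generator", "build_discriminator",
    "adversarial_value", "l2_distance", "generator_objective",
    "train_translator", "translate", "count_parameters",
]

SEG_T, SEG_C = 64, 12
PROB_EPS = 1e-7          # clamp inside log terms


@dataclass
class TranslatorConfig:
    base_feature_channels: int = 16
    n_levels: int = 3
    kernel_time: int = 5
    lambda_l2: float = 100.0
    squared_l2: bool = False          # optional ||.||^2 variant of the regularizer
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    adam_beta1: float = 0.5           # reduced first-moment decay, standard for GANs
    batch_size: int = 32
    n_epochs: int = 100
    adversarial_mode: str = "non_saturating"
    seed: int = 0

    def validate(self):
        if self.kernel_time % 2 != 1 or self.kernel_time < 1:
            raise ConfigurationError("kernel_time must be odd and positive")
        if self.n_levels < 1 or SEG_T % (2 ** self.n_levels) != 0:
            raise ConfigurationError(
                f"segment length {SEG_T} must be divisible by 2^n_levels")
        if self.lambda_l2 < 0:
            raise InvalidParameterError("lambda_l2 must be non-negative")
        if self.adversarial_mode not in ("minimax", "non_saturating"):
            raise ConfigurationError("adversarial_mode must be minimax or non_saturating")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.n_epochs < 1:
            raise InvalidParameterError("learning_rate, batch_size, n_epochs must be positive")


class ChannelScaler:
    """Per-channel standardization fitted on training segments (n, 64, 12)."""

    def __init__(self):
        self.mean: np.ndarray | None = None
        self.std: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "ChannelScaler":
        self.mean = x.mean(axis=(0, 1))
        self.std = np.maximum(x.std(axis=(0, 1)), 1e-8)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.std + self.mean


# ------------------------------------------------------------------ architecture
class _EncBlock(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng):
        self.conv = Conv1d(c_in, c_out, k, rng)
        self.norm = TimeNorm(c_out)
        self.pool = AvgPool1d(2)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.norm(self.conv(x)).relu()
        return self.pool(h), h        # pooled features, skip connection


class _DecBlock(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng):
        self.reduce = Conv1d(c_in, c_out, 1, rng)
        self.conv1 = Conv1d(2 * c_out, c_out, k, rng)
        self.conv2 = Conv1d(c_out, c_out, k, rng)
        self.norm = TimeNorm(c_out)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        h = self.reduce(upsample_linear_2x(x))
        h = concat([h, skip], axis=1)
        h = self.conv1(h).relu()
        h = self.conv2(h).relu()
        return self.norm(h)


class UNetGenerator(Module):
    """1-D U-net over time: (B, 12, 64) -> (B, 12, 64)."""

    def __init__(self, cfg: TranslatorConfig, rng: np.random.Generator):
        cfg.validate()
        widths = [cfg.base_feature_channels * 2 ** i for i in range(cfg.n_levels)]
        self.enc = []
        c_prev = SEG_C
        for w in widths:
            self.enc.append(_EncBlock(c_prev, w, cfg.kernel_time, rng))
            c_prev = w
        self.bottleneck_conv = Conv1d(widths[-1], 2 * widths[-1], cfg.kernel_time, rng)
        self.bottleneck_norm = TimeNorm(2 * widths[-1])
        self.dec = []
        c_prev = 2 * widths[-1]
        for w in reversed(widths):
            self.dec.append(_DecBlock(c_prev, w, cfg.kernel_time, rng))
            c_prev = w
        self.head_conv = Conv1d(widths[0], widths[0], 1, rng)
        self.head_dense = Conv1d(widths[0], SEG_C, 1, rng)  # time-distributed dense

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1:] != (SEG_C, SEG_T):
            raise ShapeError(f"generator input must be (batch, {SEG_C}, {SEG_T})")
        skips = []
        h = x
        for blk in self.enc:
            h, s = blk(h)
            skips.append(s)
        h = self.bottleneck_norm(self.bottleneck_conv(h)).relu()
        for blk, s in zip(self.dec, reversed(skips)):
            h = blk(h, s)
        return self.head_dense(self.head_conv(h).relu())


class Discriminator(Module):
    """Conditional discriminator on the (scalp, intracranial) concatenation.

    Input (B, 24, 64): scalp channels 1-12, intracranial channels 13-24.
    """

    WIDTHS = (32, 64, 128)

    def __init__(self, cfg: TranslatorConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None):
        cfg.validate()
        dropout_rng = dropout_rng if dropout_rng is not None else np.random.default_rng(0)
        self.blocks = []
        c_prev = 2 * SEG_C
        for w in self.WIDTHS:
            self.blocks.append([Conv1d(c_prev, w, cfg.kernel_time, rng),
                                Dropout(cfg.dropout_rate, dropout_rng),
                                MaxPool1d(2)])
            c_prev = w
        t_out = SEG_T // 2 ** len(self.WIDTHS)
        self.dense = Dense(self.WIDTHS[-1] * t_out, 1, rng)

    def forward(self, xy: Tensor) -> Tensor:
        if xy.shape[1:] != (2 * SEG_C, SEG_T):
            raise ShapeError(f"discriminator input must be (batch, {2 * SEG_C}, {SEG_T})")
        h = xy
        for conv, drop, pool in self.blocks:
            h = pool(drop(conv(h).relu()))
        h = h.reshape(h.shape[0], -1)
        return self.dense(h).sigmoid()


def build_generator(cfg: TranslatorConfig,
                    rng: np.random.Generator | None = None) -> UNetGenerator:
    rng = rng if rng is not None else \
        np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 1])))
    return UNetGenerator(cfg, rng)


def build_discriminator(cfg: TranslatorConfig, rng: np.random.Generator | None = None,
                        dropout_rng: np.random.Generator | None = None) -> Discriminator:
    rng = rng if rng is not None else \
        np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 2])))
    return Discriminator(cfg, rng, dropout_rng)


# ------------------------------------------------------------------------ losses
def adversarial_value(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Batch estimate of E[log D(X,Y)] + E[log(1 - D(X, G(X)))]."""
    d_real = np.asarray(d_real, dtype=float).ravel()
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise InvalidInputError("adversarial_value requires non-empty batches")
    d_real = np.clip(d_real, PROB_EPS, 1 - PROB_EPS)
    d_fake = np.clip(d_fake, PROB_EPS, 1 - PROB_EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def l2_distance(y_true: np.ndarray, y_est: np.ndarray) -> float:
    """Batch mean of the per-segment Euclidean (Frobenius) norm ||Y - Ỹ||₂."""
    y_true = np.asarray(y_true, dtype=float)
    y_est = np.asarray(y_est, dtype=float)
    if y_true.shape != y_est.shape:
        raise ShapeError(f"shape mismatch: {y_true.shape} vs {y_est.shape}")
    if y_true.ndim == 2:
        y_true, y_est = y_true[None], y_est[None]
    diff = (y_true - y_est).reshape(y_true.shape[0], -1)
    return float(np.mean(np.linalg.norm(diff, axis=1)))


def generator_objective(d_fake: np.ndarray, y_true: np.ndarray, y_est: np.ndarray,
                        lambda_l2: float, mode: str = "non_saturating") -> float:
    """Generator loss: adversarial term + lambda * L2 distance."""
    if lambda_l2 < 0:
        raise InvalidParameterError("lambda_l2 must be non-negative")
    d_fake = np.clip(np.asarray(d_fake, dtype=float).ravel(), PROB_EPS, 1 - PROB_EPS)
    if d_fake.size == 0:
        raise InvalidInputError("empty batch")
    if mode == "minimax":
        adv = float(np.mean(np.log(1.0 - d_fake)))
    elif mode == "non_saturating":
        adv = float(-np.mean(np.log(d_fake)))
    else:
        raise ConfigurationError(f"unknown adversarial mode {mode!r}")
    return adv + lambda_l2 * l2_distance(y_true, y_est)


def _l2_tensor(y_true: Tensor, y_est: Tensor, squared: bool) -> Tensor:
    diff = y_true - y_est
    per_seg = (diff ** 2.0).reshape(diff.shape[0], -1).sum(axis=1)
    if not squared:
        per_seg = (per_seg + 1e-12).sqrt()
    return per_seg.mean()


# ---------------------------------------------------------------------- training
@dataclass
class TrainedTranslator:
    """Fitted generator/discriminator pair with scalers and loss history."""

    generator: UNetGenerator
    discriminator: Discriminator
    config: TranslatorConfig
    x_scaler: ChannelScaler
    y_scaler: ChannelScaler
    loss_history: list[dict] = field(default_factory=list)


def train_translator(train: SegmentSet, cfg: TranslatorConfig) -> TrainedTranslator:
    """Alternating adversarial training; deterministic given (data, config, seed)."""
    cfg.validate()
    if len(train) == 0:
        raise InvalidInputError("empty training set")
    x = train.stack_x()
    y = train.stack_y()     # raises if any segment lacks intracranial ground truth

    ss = np.random.SeedSequence([cfg.seed, 0x7A])
    g_init, d_init, drop_rng, batch_rng = \
        (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4))
    gen = UNetGenerator(cfg, g_init)
    disc = Discriminator(cfg, d_init, drop_rng)
    x_scaler = ChannelScaler().fit(x)
    y_scaler = ChannelScaler().fit(y)
    xs = x_scaler.transform(x).transpose(0, 2, 1).astype(np.float32)   # (n, 12, 64)
    ys = y_scaler.transform(y).transpose(0, 2, 1).astype(np.float32)

    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate, betas=(cfg.adam_beta1, 0.999))
    opt_d = Adam(disc.parameters(), lr=cfg.learning_rate, betas=(cfg.adam_beta1, 0.999))
    n = len(train)
    history: list[dict] = []
    gen.train()
    disc.train()
    for epoch in range(cfg.n_epochs):
        perm = batch_rng.permutation(n)
        ep_gan, ep_l2, ep_l2_uv, ep_g, nb = 0.0, 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = Tensor(xs[idx]), Tensor(ys[idx])

            # --- discriminator step: ascend the adversarial value
            fake = gen(xb).detach()
            d_real = disc(concat([xb, yb], axis=1)).clip(PROB_EPS, 1 - PROB_EPS)
            d_fake = disc(concat([xb, fake], axis=1)).clip(PROB_EPS, 1 - PROB_EPS)
            adv = d_real.log().mean() + (1.0 - d_fake).log().mean()
            loss_d = -adv
            gen.zero_grad()
            disc.zero_grad()
            loss_d.backward()
            opt_d.step()

            # --- generator step: descend adversarial term + lambda * L2
            fake = gen(xb)
            d_fake_g = disc(concat([xb, fake], axis=1)).clip(PROB_EPS, 1 - PROB_EPS)
            if cfg.adversarial_mode == "minimax":
                adv_g = (1.0 - d_fake_g).log().mean()
            else:
                adv_g = -(d_fake_g.log().mean())
            l2 = _l2_tensor(yb, fake, cfg.squared_l2)
            loss_g = adv_g + cfg.lambda_l2 * l2
            gen.zero_grad()
            disc.zero_grad()
            loss_g.backward()
            opt_g.step()

            est_uv = y_scaler.inverse(fake.data.transpose(0, 2, 1))
            ep_gan += adv.item()
            ep_l2 += l2.item()
            ep_l2_uv += l2_distance(y[idx], est_uv)
            ep_g += loss_g.item()
            nb += 1
        history.append({"epoch": epoch, "l_gan": ep_gan / nb, "l2": ep_l2 / nb,
                        "l2_uv": ep_l2_uv / nb, "l_g": ep_g / nb})
    gen.eval()
    disc.eval()
    return TrainedTranslator(gen, disc, cfg, x_scaler, y_scaler, history)


def translate(model: TrainedTranslator, x: np.ndarray,
              chunk: int = 256) -> np.ndarray:
    """Apply the fitted generator: (n, 64, 12) scalp µV -> (n, 64, 12) iEEG µV."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (SEG_T, SEG_C):
        raise ShapeError(f"input must be (n, {SEG_T}, {SEG_C}), got {x.shape}")
    model.generator.eval()
    xs = model.x_scaler.transform(x).transpose(0, 2, 1).astype(np.float32)
    outs = []
    for i in range(0, len(xs), chunk):
        outs.append(model.generator(Tensor(xs[i:i + chunk])).data)
    est = np.concatenate(outs, axis=0) if outs else np.empty((0, SEG_C, SEG_T))
    return model.y_scaler.inverse(est.transpose(0, 2, 1))


def count_parameters(model) -> int:
    """Trainable scalar count of a module, or generator + discriminator of a fit."""
    if isinstance(model, TrainedTranslator):
        return model.generator.n_parameters() + model.discriminator.n_parameters()
    if isinstance(model, Module):
        return model.n_parameters()
    raise InvalidInputError("expected a TrainedTranslator or a Module")
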