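"""Modified EEGNet binary IED classifier.

EEGNet's compact topology — a temporal convolution shared across channels, a
depthwise spatial convolution collapsing the 12 channels, a separable temporal
convolution, ELU activations, pooling, dropout and a single sigmoid output —
with two modifications: every batch-normalization stage is removed, and every
pooling stage uses max pooling.  Hyperparameters follow the EEGNet defaults
(F1 = 8 temporal filters, depth multiplier D = 2, F2 = 16 separable filters);
the temporal kernel is 32 samples, half the segment length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import SegmentSet
from .errors import ConfigurationError, InvalidInputError, InvalidParameterError, ShapeError
from .nn import Adam, Conv1d, Dense, Dropout, MaxPool1d, Module, Tensor
from .translator import ChannelScaler

logger = logging.getLogger(__name__)

__all__ = ["DetectorConfig", "TrainedDetector", "EEGNetDetector", "build_detector",
           "train_detector", "predict_proba"]

SEG_T, SEG_C = 64, 12
PROB_EPS = 1e-7


@dataclass
class DetectorConfig:
    temporal_filters: int = 8          # F1
    depth_multiplier: int = 2          # D
    separable_filters: int = 16        # F2
    temporal_kernel: int = 32
    separable_kernel: int = 16
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_epochs: int = 100
    seed: int = 0

    def validate(self):
        if self.temporal_kernel > SEG_T:
            raise ConfigurationError("temporal kernel longer than the 64-sample segment")
        if min(self.temporal_filters, self.depth_multiplier, self.separable_filters,
               self.temporal_kernel, self.separable_kernel) < 1:
            raise ConfigurationError("all filter counts and kernels must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.n_epochs < 1:
            raise InvalidParameterError("learning_rate, batch_size, n_epochs must be positive")


class EEGNetDetector(Module):
    """(B, 12, 64) segment -> IED probability. No normalization layers; max pooling."""

    POOL1, POOL2 = 4, 8

    def __init__(self, cfg: DetectorConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None):
        cfg.validate()
        dropout_rng = dropout_rng if dropout_rng is not None else np.random.default_rng(0)
        f1, d, f2 = cfg.temporal_filters, cfg.depth_multiplier, cfg.separable_filters
        self.f1, self.d = f1, d
        self.conv_temporal = Conv1d(1, f1, cfg.temporal_kernel, rng, bias=False)
        self.conv_spatial = Conv1d(f1 * SEG_C, f1 * d, 1, rng, groups=f1, bias=False)
        self.pool1 = MaxPool1d(self.POOL1)
        self.drop1 = Dropout(cfg.dropout_rate, dropout_rng)
        self.conv_depthwise = Conv1d(f1 * d, f1 * d, cfg.separable_kernel, rng,
                                     groups=f1 * d, bias=False)
        self.conv_pointwise = Conv1d(f1 * d, f2, 1, rng)
        self.pool2 = MaxPool1d(self.POOL2)
        self.drop2 = Dropout(cfg.dropout_rate, dropout_rng)
        t_out = SEG_T // (self.POOL1 * self.POOL2)
        self.dense = Dense(f2 * t_out, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1:] != (SEG_C, SEG_T):
            raise ShapeError(f"detector input must be (batch, {SEG_C}, {SEG_T})")
        b = x.shape[0]
        # shared temporal filtering of every channel, regrouped filter-major
        h = x.reshape(b * SEG_C, 1, SEG_T)
        h = self.conv_temporal(h)
        h = h.reshape(b, SEG_C, self.f1, SEG_T).transpose(0, 2, 1, 3)
        h = h.reshape(b, self.f1 * SEG_C, SEG_T)
        h = self.conv_spatial(h).elu()
        h = self.drop1(self.pool1(h))
        h = self.conv_pointwise(self.conv_depthwise(h)).elu()
        h = self.drop2(self.pool2(h))
        h = h.reshape(b, -1)
        return self.dense(h).sigmoid()


def build_detector(cfg: DetectorConfig,
                   rng: np.random.Generator | None = None) -> EEGNetDetector:
    rng = rng if rng is not None else \
        np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 3])))
    return EEGNetDetector(cfg, rng)


@dataclass
class TrainedDetector:
    model: EEGNetDetector
    config: DetectorConfig
    scaler: ChannelScaler
    training_history: list[dict] = field(default_factory=list)


def _as_arrays(segments) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(segments, SegmentSet):
        return segments.stack_x(), segments.labels
    x = np.asarray(segments, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (SEG_T, SEG_C):
        raise ShapeError(f"expected (n, {SEG_T}, {SEG_C}) array, got {x.shape}")
    return x, None


def _forward_proba(det_model: EEGNetDetector, xs: np.ndarray, chunk: int = 512) -> np.ndarray:
    outs = []
    for i in range(0, len(xs), chunk):
        outs.append(det_model(Tensor(xs[i:i + chunk])).data.ravel())
    return np.concatenate(outs) if outs else np.empty(0)


def train_detector(train: SegmentSet, val: SegmentSet,
                   cfg: DetectorConfig) -> TrainedDetector:
    """Binary cross-entropy training; keeps the best-validation-accuracy model.

    With an empty validation set, the final-epoch model is returned (warned).
    Deterministic given (data, config, seed).
    """
    cfg.validate()
    x, labels = _as_arrays(train)
    if labels is None or len(x) == 0:
        raise InvalidInputError("training requires a labelled, non-empty SegmentSet")
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("training set contains a single class")

    ss = np.random.SeedSequence([cfg.seed, 0xD7])
    init_rng, drop_rng, batch_rng = \
        (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3))
    model = EEGNetDetector(cfg, init_rng, drop_rng)
    scaler = ChannelScaler().fit(x)
    xs = scaler.transform(x).transpose(0, 2, 1).astype(np.float32)
    yv = labels.astype(float)

    has_val = len(val) > 0
    if has_val:
        xv, lv = _as_arrays(val)
        xvs = scaler.transform(xv).transpose(0, 2, 1).astype(np.float32)
    else:
        logger.warning("empty validation set: keeping the final-epoch model")

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(xs)
    best_acc, best_state = -1.0, None
    history: list[dict] = []
    for epoch in range(cfg.n_epochs):
        model.train()
        perm = batch_rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb = Tensor(xs[idx])
            yb = yv[idx][:, None]
            p = model(xb).clip(PROB_EPS, 1 - PROB_EPS)
            loss = -((Tensor(yb) * p.log() + Tensor(1.0 - yb) * (1.0 - p).log()).mean())
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            nb += 1
        rec = {"epoch": epoch, "loss": ep_loss / nb}
        if has_val:
            model.eval()
            pv = _forward_proba(model, xvs)
            acc = float(((pv >= 0.5).astype(int) == lv).mean())
            rec["val_acc"] = acc
            if acc > best_acc:
                best_acc, best_state = acc, model.state()
        history.append(rec)
    if best_state is not None:
        model.load_state(best_state)
    model.eval()
    return TrainedDetector(model, cfg, scaler, history)


def predict_proba(det: TrainedDetector, segments) -> np.ndarray:
    """One IED probability per segment; deterministic (dropout disabled)."""
    x, _ = _as_arrays(segments)
    det.model.eval()
    xs = det.scaler.transform(x).transpose(0, 2, 1).astype(np.float32)
    return _forward_proba(det.model, xs)
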