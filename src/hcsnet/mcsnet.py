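"""MCSNet: the learned channel-synergy feature extractor.

Three stages, applied in order to a ``C x W`` window:

1. **LSTM, channel by channel** — each channel's time series is chopped into
   short non-overlapping patches (default 10 samples) and run through a
   single LSTM whose weights are shared across channels; the per-step hidden
   states form the channel's temporal feature maps. Patching shortens the
   recurrence from W steps to W/patch, which matters on CPU and loses
   nothing at these window lengths.
2. **Two-layer CNN** — same-padded 1-D convolutions along time (batch norm,
   ELU, average pooling after each), extracting temporal-frequency features
   per channel.
3. **Depthwise CNN across channels** — per-feature-map filters spanning the
   C channel axis combine the per-channel maps into muscle-synergy features;
   global average pooling over time yields the learned feature vector
   ``F_learning`` of length ``cnn2_filters * depthwise_multiplier``.

No input normalization is built in: scaling the input changes the output,
and any standardization is the training pipeline's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hcsnet import autograd as ag
from hcsnet import nn
from hcsnet.autograd import Tensor


@dataclass
class McsnetConfig:
    lstm_hidden: int = 16
    patch_len: int = 10
    cnn1_filters: int = 8
    cnn2_filters: int = 32
    kernel_len: int = 15
    depthwise_multiplier: int = 2
    pool_len: int = 2
    dropout_rate: float = 0.25

    def __post_init__(self) -> None:
        for name in ("lstm_hidden", "patch_len", "cnn1_filters", "cnn2_filters",
                     "kernel_len", "depthwise_multiplier", "pool_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def feature_dim(self) -> int:
        return self.cnn2_filters * self.depthwise_multiplier


class MCSNet(nn.Module):
    """LSTM -> CNN x2 -> depthwise-CNN feature extractor."""

    def __init__(self, cfg: McsnetConfig, input_shape: tuple[int, int], seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.n_channels, self.window_len = input_shape
        if self.window_len < cfg.patch_len:
            raise ValueError(f"window length {self.window_len} < patch_len {cfg.patch_len}")
        self.n_steps = self.window_len // cfg.patch_len
        t1 = self.n_steps // cfg.pool_len
        t2 = t1 // cfg.pool_len
        if cfg.kernel_len > self.n_steps:
            raise ValueError(
                f"kernel_len {cfg.kernel_len} exceeds LSTM sequence length {self.n_steps}"
            )
        if t1 < 1 or t2 < 1:
            raise ValueError(
                f"pooling (pool_len {cfg.pool_len}) collapses the sequence "
                f"({self.n_steps} -> {t1} -> {t2}); reduce pool_len or kernel/patch sizes"
            )
        if cfg.kernel_len > t1:
            raise ValueError(f"kernel_len {cfg.kernel_len} exceeds pooled sequence length {t1}")
        rng = np.random.default_rng(seed)
        self.lstm = self.add_child(nn.LSTM(cfg.patch_len, cfg.lstm_hidden, rng))
        self.conv1 = self.add_child(nn.Conv1dSame(cfg.lstm_hidden, cfg.cnn1_filters, cfg.kernel_len, rng))
        self.bn1 = self.add_child(nn.BatchNorm1d(cfg.cnn1_filters))
        self.conv2 = self.add_child(nn.Conv1dSame(cfg.cnn1_filters, cfg.cnn2_filters, cfg.kernel_len, rng))
        self.bn2 = self.add_child(nn.BatchNorm1d(cfg.cnn2_filters))
        self.depthwise = self.add_child(
            nn.DepthwiseChannelMix(self.n_channels, cfg.cnn2_filters, cfg.depthwise_multiplier, rng)
        )
        self._dropout_rng = np.random.default_rng(seed + 1)
        self.t2 = t2

    @property
    def feature_dim(self) -> int:
        return self.cfg.feature_dim

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, W) windows -> (B, feature_dim) learned features."""
        b, c, w = x.shape
        if (c, w) != (self.n_channels, self.window_len):
            raise ValueError(
                f"window shape mismatch: expected {(self.n_channels, self.window_len)}, got {(c, w)}"
            )
        cfg = self.cfg
        w_used = self.n_steps * cfg.patch_len
        if w_used != w:
            x = ag.getitem(x, (slice(None), slice(None), slice(0, w_used)))
        seq = ag.reshape(x, (b * c, self.n_steps, cfg.patch_len))
        h = self.lstm.forward(seq)  # (B*C, H, T)
        h = nn.avg_pool1d(ag.elu(self.bn1.forward(self.conv1.forward(h))), cfg.pool_len)
        h = nn.avg_pool1d(ag.elu(self.bn2.forward(self.conv2.forward(h))), cfg.pool_len)
        h = ag.reshape(h, (b, c, cfg.cnn2_filters, self.t2))
        h = ag.elu(self.depthwise.forward(h))  # (B, F2*mult, T2)
        h = ag.dropout(h, cfg.dropout_rate, self._dropout_rng, self.training)
        return ag.tmean(h, axis=2)


def build_mcsnet(cfg: McsnetConfig, input_shape: tuple[int, int], seed: int = 0) -> MCSNet:
    """Build the extractor; raises on kernel/pool sizes the input cannot support."""
    return MCSNet(cfg, input_shape, seed=seed)


def parameter_count(cfg: McsnetConfig, input_shape: tuple[int, int]) -> int:
    """Closed-form parameter count for a given config and input shape."""
    c, _ = input_shape
    h, k = cfg.lstm_hidden, cfg.kernel_len
    f1, f2, m = cfg.cnn1_filters, cfg.cnn2_filters, cfg.depthwise_multiplier
    lstm = (cfg.patch_len + h) * 4 * h + 4 * h
    conv1 = f1 * h * k + f1 + 2 * f1  # weights + bias + BN gamma/beta
    conv2 = f2 * f1 * k + f2 + 2 * f2
    depthwise = f2 * m * c + f2 * m
    return lstm + conv1 + conv2 + depthwise


def mcsnet_forward(model: MCSNet, windows: np.ndarray) -> np.ndarray:
    """Deterministic eval-mode forward over a (B, C, W) stack."""
    was_training = model.training
    model.eval()
    out = model.forward(Tensor(np.asarray(windows, dtype=float))).data
    model.train(was_training)
    return out
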