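"""Feature fusion by channel attention, classification, and training.

The fused vector is the concatenation ``[F_td | F_fd | F_learning]``. A
channel-attention block groups it into attention channels — one group per
sEMG channel's time-domain block, one per frequency-domain block, and one
per learned feature map — then gates each group:

    w_g = sigmoid( MLP(avg_g) + MLP(max_g) ),      F = w (broadcast) * F_fusion

with a single shared two-layer MLP (bottleneck ``n_groups / reduction``,
ELU inside). The literal reading of the gating as a matrix product is
shape-inconsistent for a flat feature vector, so the standard
channel-attention broadcast multiply is used. A ``flat_attention`` mode
instead treats every element as its own channel (pooling degenerates to the
identity).

Classification is ``softmax(linear(F))`` over the three movements. Training
minimizes class-weighted categorical cross-entropy with Adam (default
hyperparameters), runs at most ``max_epochs`` epochs, and keeps the weights
from the epoch with the lowest validation loss (validation stopping). The
hand-crafted blocks enter the graph as constants, z-scored with statistics
fit on the training split; gradients flow through MCSNet, attention, and
the head jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from hcsnet import autograd as ag
from hcsnet import nn
from hcsnet.autograd import Tensor
from hcsnet.mcsnet import MCSNet, McsnetConfig
from hcsnet.signal_io import CLASSES


@dataclass
class FusedFeature:
    f_fusion: np.ndarray
    channel_weights: np.ndarray | None = None
    f_final: np.ndarray | None = None


@dataclass
class PredictedLabel:
    probabilities: np.ndarray
    label: str


@dataclass
class TrainConfig:
    max_epochs: int = 1000
    batch_size: int = 64
    seed: int = 0
    attention_reduction: int = 4
    normalize_handcrafted: bool = True
    early_stop_patience: int = 12  # epochs without meaningful val-loss improvement; <=0 disables
    early_stop_min_delta: float = 1e-3  # improvement below this does not reset patience
    feature_sources: tuple[str, ...] = ("handcrafted", "learned")
    flat_attention: bool = False

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.attention_reduction < 1:
            raise ValueError("attention_reduction must be >= 1")
        for s in self.feature_sources:
            if s not in ("handcrafted", "learned"):
                raise ValueError(f"unknown feature source {s!r}")
        if not self.feature_sources:
            raise ValueError("at least one feature source is required")


def concat_features(td: np.ndarray, fd: np.ndarray, learned: np.ndarray) -> FusedFeature:
    """``F_fusion = [F_td, F_fd, F_learning]`` for a batch; all blocks mandatory."""
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in (td, fd, learned)]
    for name, b in zip(("td", "fd", "learned"), blocks):
        if b.shape[1] == 0:
            raise ValueError(f"feature block {name!r} is empty; all three sources are mandatory")
    n = {b.shape[0] for b in blocks}
    if len(n) != 1:
        raise ValueError(f"mismatched batch sizes across blocks: {[b.shape[0] for b in blocks]}")
    return FusedFeature(f_fusion=np.concatenate(blocks, axis=1))


def attention_groups(
    n_channels: int, n_td_per_ch: int, n_fd_per_ch: int, learned_dim: int, flat: bool = False
) -> np.ndarray:
    """Sizes of the contiguous attention channels covering the fused layout."""
    if flat:
        return np.ones(n_channels * (n_td_per_ch + n_fd_per_ch) + learned_dim, dtype=int)
    sizes = [n_td_per_ch] * n_channels + [n_fd_per_ch] * n_channels + [1] * learned_dim
    return np.asarray(sizes, dtype=int)


class ChannelAttention(nn.Module):
    """Shared-MLP avg/max channel attention over contiguous feature groups."""

    def __init__(self, group_sizes: np.ndarray, reduction: int, rng: np.random.Generator):
        super().__init__()
        self.group_sizes = np.asarray(group_sizes, dtype=int)
        if np.any(self.group_sizes < 1):
            raise ValueError("every attention channel must contain at least one element")
        self.starts = np.concatenate([[0], np.cumsum(self.group_sizes)[:-1]])
        g = len(self.group_sizes)
        bottleneck = max(1, g // reduction)
        self.fc1 = self.add_child(nn.Linear(g, bottleneck, rng))
        self.fc2 = self.add_child(nn.Linear(bottleneck, g, rng))

    def check_cover(self, dim: int) -> None:
        if int(self.group_sizes.sum()) != dim:
            raise ValueError(
                f"attention channels cover {int(self.group_sizes.sum())} elements "
                f"but the fused vector has {dim}"
            )

    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2.forward(ag.elu(self.fc1.forward(x)))

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (gated features, attention weights)."""
        self.check_cover(f.shape[1])
        avg = ag.segment_mean(f, self.starts, self.group_sizes)
        mx = ag.segment_max(f, self.starts, self.group_sizes)
        w = ag.sigmoid(self._mlp(avg) + self._mlp(mx))
        return ag.segment_scale(f, w, self.group_sizes), w


def channel_attention(f: FusedFeature, module: ChannelAttention) -> FusedFeature:
    """Functional eval-mode attention pass over a :class:`FusedFeature`."""
    x = Tensor(np.atleast_2d(f.f_fusion))
    gated, w = module.forward(x)
    return FusedFeature(f_fusion=f.f_fusion, channel_weights=w.data, f_final=gated.data)


def classify(f_final: np.ndarray, head: nn.Linear) -> list[PredictedLabel]:
    """``softmax(linear(F))``; argmax label, ties toward the lowest class index."""
    logits = Tensor(np.atleast_2d(f_final)) @ head.w + head.b
    p = ag.softmax(logits.data)
    return [PredictedLabel(probabilities=row, label=CLASSES[int(np.argmax(row))]) for row in p]


def class_weights(labels: Sequence[int] | np.ndarray) -> np.ndarray:
    """Inverse-proportion class weights with the majority class at exactly 1."""
    labels = np.asarray(labels)
    counts = np.array([np.sum(labels == k) for k in range(len(CLASSES))], dtype=float)
    if np.any(counts == 0):
        missing = [CLASSES[k] for k in np.flatnonzero(counts == 0)]
        raise ValueError(f"class(es) absent from training labels: {missing}")
    return counts.max() / counts


class HCSNetModel(nn.Module):
    """MCSNet + channel attention + linear softmax head."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        handcrafted_dims: tuple[int, int],  # (td_per_channel, fd_per_channel)
        mcsnet_cfg: McsnetConfig | None = None,
        train_cfg: TrainConfig | None = None,
        seed: int = 0,
    ):
        super().__init__()
        self.input_shape = input_shape
        self.mcsnet_cfg = mcsnet_cfg or McsnetConfig()
        self.train_cfg = train_cfg or TrainConfig()
        self.handcrafted_dims = handcrafted_dims
        c = input_shape[0]
        n_td, n_fd = handcrafted_dims
        use_hand = "handcrafted" in self.train_cfg.feature_sources
        self.use_learned = "learned" in self.train_cfg.feature_sources
        self.use_handcrafted = use_hand

        rng = np.random.default_rng(seed)
        learned_dim = self.mcsnet_cfg.feature_dim if self.use_learned else 0
        if self.use_learned:
            self.mcsnet = self.add_child(MCSNet(self.mcsnet_cfg, input_shape, seed=seed + 1))
        else:
            self.mcsnet = None
        sizes = []
        if use_hand:
            sizes.append(attention_groups(c, n_td, n_fd, 0, flat=self.train_cfg.flat_attention))
        if self.use_learned:
            sizes.append(np.ones(learned_dim, dtype=int))
        group_sizes = np.concatenate(sizes)
        self.attention = self.add_child(
            ChannelAttention(group_sizes, self.train_cfg.attention_reduction, rng)
        )
        self.fused_dim = int(group_sizes.sum())
        self.head = self.add_child(nn.Linear(self.fused_dim, len(CLASSES), rng))
        # z-score statistics for the hand-crafted block, fit on the training split
        hand_dim = c * (n_td + n_fd) if use_hand else 0
        self.hand_mean = np.zeros(hand_dim)
        self.hand_std = np.ones(hand_dim)

    def fit_normalizer(self, hand: np.ndarray) -> None:
        if not self.use_handcrafted or not self.train_cfg.normalize_handcrafted:
            return
        self.hand_mean = hand.mean(axis=0)
        std = hand.std(axis=0)
        self.hand_std = np.where(std > 0, std, 1.0)

    def normalize(self, hand: np.ndarray) -> np.ndarray:
        return (hand - self.hand_mean) / self.hand_std

    def forward_logits(self, windows: np.ndarray, hand: np.ndarray) -> Tensor:
        blocks: list[Tensor] = []
        if self.use_handcrafted:
            blocks.append(Tensor(self.normalize(hand)))
        if self.use_learned:
            blocks.append(self.mcsnet.forward(Tensor(np.asarray(windows, dtype=float))))
        fused = blocks[0] if len(blocks) == 1 else ag.concat(blocks, axis=1)
        gated, _ = self.attention.forward(fused)
        return self.head.forward(gated)

    def state_arrays(self) -> list[np.ndarray]:
        return super().state_arrays() + [self.hand_mean, self.hand_std]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        *module_arrays, hand_mean, hand_std = arrays
        flat = nn.Module.state_arrays(self)
        if len(flat) != len(module_arrays):
            raise ValueError(f"state mismatch: have {len(flat)} arrays, got {len(module_arrays)}")
        for dst, src in zip(flat, module_arrays):
            dst[...] = src
        self.hand_mean = hand_mean.copy()
        self.hand_std = hand_std.copy()


def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.argmax(logits, axis=1) == labels))


def train(
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    model_cfg: McsnetConfig | None = None,
    train_cfg: TrainConfig | None = None,
    handcrafted_dims: tuple[int, int] = (12, 3),
) -> tuple[HCSNetModel, list[dict]]:
    """Train on (windows, handcrafted, labels) triples; validation stopping.

    Returns the model restored to its best-validation-loss epoch and the
    per-epoch history (``epoch, train_loss, val_loss, train_acc, val_acc``).
    Deterministic for a fixed ``train_cfg.seed``.
    """
    train_cfg = train_cfg or TrainConfig()
    xw, xh, y = train_data
    vw, vh, vy = val_data
    if len(y) == 0 or len(vy) == 0:
        raise ValueError("empty training or validation split")
    if len(np.unique(y)) < 2:
        raise ValueError("training split contains a single class")
    model = HCSNetModel(
        input_shape=tuple(xw.shape[1:]),
        handcrafted_dims=handcrafted_dims,
        mcsnet_cfg=model_cfg,
        train_cfg=train_cfg,
        seed=train_cfg.seed,
    )
    model.fit_normalizer(xh)
    weights = class_weights(y)
    opt = nn.Adam(model.parameters())
    rng = np.random.default_rng(train_cfg.seed + 7)
    if model.mcsnet is not None:
        model.mcsnet.reseed_dropout(train_cfg.seed + 13)

    n = len(y)
    history: list[dict] = []
    best = {"val_loss": np.inf, "epoch": -1, "state": None}
    since_best = 0
    for epoch in range(train_cfg.max_epochs):
        model.train(True)
        order = rng.permutation(n)
        tr_loss = 0.0
        tr_correct = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            logits = model.forward_logits(xw[idx], xh[idx])
            loss = ag.weighted_cross_entropy(logits, y[idx], weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tr_loss += float(loss.data) * len(idx)
            tr_correct += int(np.sum(np.argmax(logits.data, axis=1) == y[idx]))
        model.eval()
        val_logits = _eval_logits(model, vw, vh, train_cfg.batch_size)
        val_loss = float(
            ag.weighted_cross_entropy(Tensor(val_logits), vy, weights).data
        )
        rec = {
            "epoch": epoch,
            "train_loss": tr_loss / n,
            "val_loss": val_loss,
            "train_acc": tr_correct / n,
            "val_acc": _accuracy(val_logits, vy),
        }
        history.append(rec)
        meaningful = val_loss < best["val_loss"] - train_cfg.early_stop_min_delta
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "epoch": epoch,
                    "state": [a.copy() for a in model.state_arrays()]}
        if meaningful:
            since_best = 0
        else:
            since_best += 1
            if train_cfg.early_stop_patience > 0 and since_best >= train_cfg.early_stop_patience:
                break
    model.load_state_arrays(best["state"])
    model.best_epoch = best["epoch"]
    model.eval()
    return model, history


def _eval_logits(model: HCSNetModel, windows: np.ndarray, hand: np.ndarray, batch: int) -> np.ndarray:
    outs = []
    for start in range(0, len(hand), batch):
        outs.append(model.forward_logits(windows[start : start + batch],
                                         hand[start : start + batch]).data)
    return np.concatenate(outs, axis=0)


def predict(model: HCSNetModel, windows: np.ndarray, hand: np.ndarray) -> list[PredictedLabel]:
    """Eval-mode predictions; independent of batch composition."""
    model.eval()
    logits = _eval_logits(model, windows, hand, model.train_cfg.batch_size)
    probs = ag.softmax(logits)
    return [PredictedLabel(probabilities=row, label=CLASSES[int(np.argmax(row))]) for row in probs]


def history_to_csv(history: list[dict], path) -> None:
    lines = ["epoch,train_loss,val_loss,train_acc,val_acc"]
    for r in history:
        lines.append(
            f"{r['epoch']},{r['train_loss']:.8f},{r['val_loss']:.8f},"
            f"{r['train_acc']:.6f},{r['val_acc']:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_checkpoint(model: HCSNetModel, path) -> None:
    """Single-file checkpoint: config JSON + all weight/buffer arrays."""
    meta = {
        "input_shape": list(model.input_shape),
        "handcrafted_dims": list(model.handcrafted_dims),
        "mcsnet_cfg": asdict(model.mcsnet_cfg),
        "train_cfg": {**asdict(model.train_cfg),
                      "feature_sources": list(model.train_cfg.feature_sources)},
    }
    arrays = {f"arr{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> HCSNetModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"arr{i}"] for i in range(len(data.files) - 1)]
    tc = meta["train_cfg"]
    tc["feature_sources"] = tuple(tc["feature_sources"])
    model = HCSNetModel(
        input_shape=tuple(meta["input_shape"]),
        handcrafted_dims=tuple(meta["handcrafted_dims"]),
        mcsnet_cfg=McsnetConfig(**meta["mcsnet_cfg"]),
        train_cfg=TrainConfig(**tc),
        seed=0,
    )
    model.load_state_arrays(arrays)
    model.eval()
    return model
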