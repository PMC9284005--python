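"""Attention gating, classification head, class weights, and training loop."""

import numpy as np
import pytest

from hcsnet import autograd as ag
from hcsnet import nn
from hcsnet.autograd import Tensor
from hcsnet.fusion_model import (
    ChannelAttention,
    FusedFeature,
    HCSNetModel,
    TrainConfig,
    attention_groups,
    channel_attention,
    class_weights,
    classify,
    concat_features,
    history_to_csv,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from hcsnet.mcsnet import McsnetConfig

SMALL_NET = McsnetConfig(lstm_hidden=6, patch_len=10, cnn1_filters=4, cnn2_filters=8,
                         kernel_len=5, depthwise_multiplier=2, pool_len=2, dropout_rate=0.0)


def _toy_data(rng, n=90):
    """Three classes separated in both windows and hand-crafted features."""
    t = np.arange(300) / 1500.0
    xw = np.empty((n, 5, 300))
    xh = np.empty((n, 75))
    y = np.arange(n) % 3
    for i in range(n):
        freq = [60.0, 150.0, 240.0][y[i]]
        xw[i] = (1 + y[i]) * np.sin(2 * np.pi * freq * t) + 0.05 * rng.standard_normal((5, 300))
        xh[i] = y[i] + 0.1 * rng.standard_normal(75)
    return xw, xh, y


class TestConcat:
    def test_order_and_length(self, rng):
        td, fd, lr = rng.standard_normal((2, 60)), rng.standard_normal((2, 15)), rng.standard_normal((2, 64))
        f = concat_features(td, fd, lr)
        assert f.f_fusion.shape == (2, 139)
        assert np.array_equal(f.f_fusion[:, :60], td)
        assert np.array_equal(f.f_fusion[:, 60:75], fd)
        assert np.array_equal(f.f_fusion[:, 75:], lr)

    def test_empty_block_rejected(self, rng):
        with pytest.raises(ValueError, match="mandatory"):
            concat_features(rng.standard_normal((2, 60)), np.empty((2, 0)), rng.standard_normal((2, 64)))

    def test_mismatched_batches_rejected(self, rng):
        with pytest.raises(ValueError, match="batch"):
            concat_features(rng.standard_normal((2, 6)), rng.standard_normal((3, 3)), rng.standard_normal((2, 4)))


class TestAttention:
    def _module(self, rng, groups=None, reduction=4):
        groups = groups if groups is not None else attention_groups(5, 12, 3, 64)
        return ChannelAttention(groups, reduction, rng)

    def test_zero_mlp_gives_half_weights(self, rng):
        mod = self._module(rng)
        for p in mod.parameters():
            p.data[...] = 0.0
        f = FusedFeature(f_fusion=rng.standard_normal((3, 139)))
        out = channel_attention(f, mod)
        assert np.allclose(out.channel_weights, 0.5)
        assert np.allclose(out.f_final, 0.5 * f.f_fusion)

    def test_weights_strictly_in_unit_interval(self, rng):
        mod = self._module(rng)
        out = channel_attention(FusedFeature(rng.standard_normal((8, 139)) * 10), mod)
        assert np.all(out.channel_weights > 0) and np.all(out.channel_weights < 1)

    def test_layout_preserved_and_zero_slice_stays_zero(self, rng):
        mod = self._module(rng)
        f = rng.standard_normal((2, 139))
        f[:, :12] = 0.0  # first sEMG channel's time-domain block
        out = channel_attention(FusedFeature(f), mod)
        assert out.f_final.shape == f.shape
        assert np.allclose(out.f_final[:, :12], 0.0)

    def test_grouping_must_cover_vector(self, rng):
        mod = self._module(rng, groups=np.array([5, 5]))
        with pytest.raises(ValueError, match="cover"):
            channel_attention(FusedFeature(rng.standard_normal((2, 139))), mod)

    def test_flat_attention_is_elementwise(self, rng):
        groups = attention_groups(5, 12, 3, 64, flat=True)
        assert groups.sum() == 139 and len(groups) == 139


class TestClassify:
    def test_zero_head_uniform(self, rng):
        head = nn.Linear(10, 3, rng)
        head.w.data[...] = 0.0
        head.b.data[...] = 0.0
        preds = classify(rng.standard_normal((4, 10)), head)
        for p in preds:
            assert np.allclose(p.probabilities, 1 / 3)
            assert p.label == "standing"  # ties break toward lowest class index

    def test_dominant_logit(self, rng):
        head = nn.Linear(3, 3, rng)
        head.w.data[...] = 0.0
        head.b.data[...] = np.array([10.0, 0.0, 0.0])
        p = classify(np.zeros((1, 3)), head)[0]
        assert p.label == "standing" and p.probabilities[0] > 0.99

    def test_probabilities_sum_to_one(self, rng):
        head = nn.Linear(7, 3, rng)
        preds = classify(rng.standard_normal((20, 7)) * 5, head)
        for p in preds:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(p.probabilities >= 0)


class TestClassWeights:
    def test_majority_is_one(self):
        labels = [2] * 20 + [1] * 10 + [0] * 10  # walking majority
        w = class_weights(labels)
        assert np.allclose(w, [2.0, 2.0, 1.0])

    def test_balanced_all_ones(self):
        assert np.allclose(class_weights([0, 1, 2] * 5), 1.0)

    def test_rule_application(self):
        w = class_weights([0] * 30 + [1] * 10 + [2] * 60)
        assert np.allclose(w, [2.0, 6.0, 1.0])

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            class_weights([0, 0, 1, 1])

    def test_weight_neutrality_on_balanced_loss(self, rng):
        logits = Tensor(rng.standard_normal((12, 3)))
        y = np.array([0, 1, 2] * 4)
        lw = ag.weighted_cross_entropy(logits, y, class_weights(y))
        lu = ag.weighted_cross_entropy(logits, y, np.ones(3))
        assert float(lw.data) == pytest.approx(float(lu.data))


class TestTraining:
    def _split(self, rng):
        xw, xh, y = _toy_data(rng)
        val = np.arange(len(y)) % 5 == 0
        return (xw[~val], xh[~val], y[~val]), (xw[val], xh[val], y[val])

    def test_training_learns_and_restores_best(self, rng):
        tr, va = self._split(rng)
        cfg = TrainConfig(max_epochs=30, seed=0, early_stop_patience=0)
        model, hist = train(tr, va, model_cfg=SMALL_NET, train_cfg=cfg)
        losses = [h["val_loss"] for h in hist]
        assert hist[model.best_epoch]["val_loss"] == min(losses)
        # loss decreases over the first epochs
        assert hist[9]["train_loss"] < hist[0]["train_loss"]
        assert hist[-1]["val_acc"] >= 0.9

    def test_determinism_same_seed(self, rng, tmp_path):
        tr, va = self._split(rng)
        cfg = TrainConfig(max_epochs=8, seed=11)
        _, h1 = train(tr, va, model_cfg=SMALL_NET, train_cfg=cfg)
        _, h2 = train(tr, va, model_cfg=SMALL_NET, train_cfg=cfg)
        for a, b in zip(h1, h2):
            for k in ("train_loss", "val_loss", "train_acc", "val_acc"):
                assert a[k] == pytest.approx(b[k], abs=1e-6)
        p1, p2 = tmp_path / "h1.csv", tmp_path / "h2.csv"
        history_to_csv(h1, p1)
        history_to_csv(h2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_or_single_class_split_rejected(self, rng):
        tr, va = self._split(rng)
        with pytest.raises(ValueError):
            train((tr[0][:0], tr[1][:0], tr[2][:0]), va, model_cfg=SMALL_NET)
        mask = tr[2] == 0
        with pytest.raises(ValueError, match="single class"):
            train((tr[0][mask], tr[1][mask], tr[2][mask]), va, model_cfg=SMALL_NET)

    def test_predict_deterministic_and_batch_independent(self, rng):
        tr, va = self._split(rng)
        cfg = TrainConfig(max_epochs=5, seed=2, batch_size=16)
        model, _ = train(tr, va, model_cfg=SMALL_NET, train_cfg=cfg)
        p1 = predict(model, va[0], va[1])
        p2 = predict(model, va[0], va[1])
        assert all(np.array_equal(a.probabilities, b.probabilities) for a, b in zip(p1, p2))
        single = predict(model, va[0][:1], va[1][:1])[0]
        assert np.allclose(single.probabilities, p1[0].probabilities, atol=1e-6)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        tr, va = self._split(rng)
        model, _ = train(tr, va, model_cfg=SMALL_NET, train_cfg=TrainConfig(max_epochs=3, seed=5))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        a = predict(model, va[0], va[1])
        b = predict(back, va[0], va[1])
        assert all(np.allclose(x.probabilities, y.probabilities) for x, y in zip(a, b))


def test_ablation_fused_not_worse_than_single_sources(rng):
    """Regression tripwire: fusion should not fall behind either source alone."""
    xw, xh, y = _toy_data(rng, n=120)
    val = np.arange(len(y)) % 4 == 0
    tr = (xw[~val], xh[~val], y[~val])
    va = (xw[val], xh[val], y[val])
    accs = {}
    for sources in (("handcrafted", "learned"), ("handcrafted",), ("learned",)):
        cfg = TrainConfig(max_epochs=25, seed=0, feature_sources=sources,
                          early_stop_patience=0)
        model, hist = train(tr, va, model_cfg=SMALL_NET, train_cfg=cfg)
        preds = predict(model, va[0], va[1])
        from hcsnet.signal_io import CLASSES
        accs[sources] = np.mean([CLASSES.index(p.label) == t for p, t in zip(preds, va[2])])
    fused = accs[("handcrafted", "learned")]
    assert fused >= max(accs[("handcrafted",)], accs[("learned",)]) - 0.05
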