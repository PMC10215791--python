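"""Combo loss, augmentation, staged training/freezing/merging, quantization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesica import train_quant as tq
from vesica.exceptions import GraphMismatchError, InvalidArgumentError
from vesica.net_arch import ModelConfig, build_model
from vesica.nn.layers import BatchNorm, Conv2D
from vesica.nn.quant import QuantSpec, quantize_weights
from vesica.train_quant import arrays_from_samples


@pytest.fixture(scope="module")
def tiny_data(tiny_samples):
    samples, splits = tiny_samples
    return arrays_from_samples(samples, splits, 32)


@pytest.fixture(scope="module")
def tiny_model_cfg():
    return ModelConfig(input_size=32, seed=0)


class TestComboLoss:
    def test_perfect_prediction_gives_zero(self):
        gt = (np.random.default_rng(0).random((6, 6)) > 0.5).astype(np.uint8)
        pred = np.stack([1.0 - gt, gt], axis=-1).astype(float)
        assert tq.combo_loss(pred, gt, 0.5) == pytest.approx(0.0, abs=1e-6)

    def test_alpha_one_is_pure_cross_entropy(self):
        rng = np.random.default_rng(1)
        p1 = rng.uniform(0.05, 0.95, (5, 5))
        pred = np.stack([1 - p1, p1], -1)
        gt = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        ce = -np.mean(gt * np.log(p1) + (1 - gt) * np.log(1 - p1))
        assert tq.combo_loss(pred, gt, 1.0) == pytest.approx(ce, rel=1e-6)

    def test_alpha_zero_is_dice_loss(self):
        rng = np.random.default_rng(2)
        p1 = rng.uniform(0.05, 0.95, (5, 5))
        pred = np.stack([1 - p1, p1], -1)
        gt = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        dice = 2 * (p1 * gt).sum() / (p1.sum() + gt.sum())
        assert tq.combo_loss(pred, gt, 0.0) == pytest.approx(1 - dice, rel=1e-6)

    def test_hand_computed_single_pixel_case(self):
        # p(bladder) = 0.5, y = 1, alpha = 0.5:
        # 0.5 * (-ln 0.5) + 0.5 * (1 - 2*0.5/(0.5+1)) = 0.3466 + 0.1667
        pred = np.array([[[0.5, 0.5]]])
        gt = np.array([[1]])
        assert tq.combo_loss(pred, gt, 0.5) == pytest.approx(0.5132, abs=5e-4)

    def test_empty_tensors_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tq.combo_loss(np.zeros((0, 2)), np.zeros((0,)), 0.5)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        p1 = rng.uniform(0.1, 0.9, (4, 4))
        pred = np.stack([1 - p1, p1], -1)
        gt = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        _, grad = tq.combo_loss_with_grad(pred, gt, 0.4)
        eps = 1e-6
        for idx in [(0, 0, 1), (1, 2, 0), (3, 3, 1)]:
            pp = pred.copy()
            pp[idx] += eps
            lp = tq.combo_loss(pp, gt, 0.4)
            pp[idx] -= 2 * eps
            lm = tq.combo_loss(pp, gt, 0.4)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_loss_decomposition_property(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(1e-3, 1 - 1e-3, (3, 3))
        pred = np.stack([1 - p1, p1], -1)
        gt = (rng.random((3, 3)) > 0.5).astype(np.uint8)
        ce = tq.combo_loss(pred, gt, 1.0)
        dl = tq.combo_loss(pred, gt, 0.0)
        for alpha in (0.25, 0.5, 0.8):
            assert tq.combo_loss(pred, gt, alpha) == pytest.approx(
                alpha * ce + (1 - alpha) * dl, rel=1e-9)


class TestAugment:
    def test_flip_is_an_involution(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (8, 10), np.uint8)
        mask = rng.random((8, 10)) > 0.5
        i1, m1 = tq.augment(img, mask, shift=0, flip=True)
        i2, m2 = tq.augment(i1, m1, shift=0, flip=True)
        assert np.array_equal(i2, img) and np.array_equal(m2, mask)

    def test_intensity_shift_moves_constant_image(self):
        img = np.full((4, 4), 50, np.uint8)
        mask = np.zeros((4, 4), bool)
        out, m = tq.augment(img, mask, shift=10, flip=False)
        assert (out == 60).all() and np.array_equal(m, mask)

    def test_disabled_augmentation_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((6, 6), dtype=np.float32)
        mask = rng.random((6, 6)) > 0.5
        out, m = tq.augment(img, mask, rng, intensity_shift_range=0, lr_flip_prob=0)
        assert np.allclose(out, img) and np.array_equal(m, mask)


class TestFakeQuantize:
    def test_exact_grid_representability(self):
        w = np.array([-1.0, 0.0, 1.0], np.float32)
        codes, scale = quantize_weights(w)
        assert scale == pytest.approx(1 / 127)
        assert list(codes) == [-127, 0, 127]
        assert np.allclose(tq.fake_quantize(w), w)

    def test_all_zero_tensor(self):
        w = np.zeros(7, np.float32)
        codes, scale = quantize_weights(w)
        assert (codes == 0).all() and tq.fake_quantize(w).sum() == 0

    def test_idempotence(self):
        w = np.random.default_rng(0).normal(size=100).astype(np.float32)
        once = tq.fake_quantize(w)
        assert np.array_equal(tq.fake_quantize(once), once)

    def test_codes_stay_in_signed_8bit_range(self):
        w = np.random.default_rng(1).normal(0, 10, 500).astype(np.float32)
        codes, _ = quantize_weights(w)
        assert codes.min() >= -127 and codes.max() <= 127


class TestStagedTraining:
    def test_classification_stage_freezes_backbone_and_seg(self, tiny_data, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        before = {k: v.copy() for k, v in model.network.state_dict().items()
                  if not k.startswith("clf_")}
        cfg = tq.TrainConfig(max_epochs=2, batch_size=8, seed=0,
                             intensity_shift_range=5.0, lr_flip_prob=0.5)
        tq.train_stage(model, "classification", tiny_data, cfg)
        after = model.network.state_dict()
        for k, v in before.items():
            assert np.array_equal(v, after[k]), k

    def test_zero_learning_rate_stops_at_patience(self, tiny_data, tiny_model_cfg):
        # with nothing changing, validation loss cannot improve after the
        # first epoch, so patience=1 halts the run at epoch 2
        model = build_model(tiny_model_cfg)
        cfg = tq.TrainConfig(max_epochs=10, patience=1, learning_rate=0.0,
                             batch_size=8, seed=0,
                             intensity_shift_range=0, lr_flip_prob=0)
        _, hist = tq.train_stage(model, "classification", tiny_data, cfg)
        assert len(hist) == 2

    def test_reproducible_histories(self, tiny_data, tiny_model_cfg):
        hists = []
        for _ in range(2):
            model = build_model(tiny_model_cfg)
            cfg = tq.TrainConfig(max_epochs=2, batch_size=8, seed=11)
            _, h = tq.train_stage(model, "segmentation", tiny_data, cfg)
            hists.append(h)
        assert hists[0].equals(hists[1])

    def test_smoke_training_learns_the_synthetic_task(self, tiny_samples):
        """32 training images, 30 epochs: final train Dice exceeds 0.8."""
        samples, splits = tiny_samples
        data = arrays_from_samples(samples, splits, 96)
        model = build_model(ModelConfig(input_size=96, seed=0))
        cfg = tq.TrainConfig(max_epochs=30, batch_size=8, seed=0)
        _, hist = tq.train_stage(model, "segmentation", data, cfg)
        assert hist.train_dice.iloc[-1] > 0.8


class TestMergePaths:
    def test_merge_is_idempotent(self, tiny_model_cfg):
        w = build_model(tiny_model_cfg).network.state_dict()
        merged = tq.merge_paths(w, w)
        assert set(merged) == set(w)
        assert all(np.array_equal(merged[k], w[k]) for k in w)

    def test_mismatched_graphs_rejected(self, tiny_model_cfg):
        w = build_model(tiny_model_cfg).network.state_dict()
        other = dict(w)
        other.pop(next(iter(other)))
        with pytest.raises(GraphMismatchError):
            tq.merge_paths(w, other)

    def test_merged_outputs_equal_stage_outputs_bitwise(self, tiny_data, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        cfg = tq.TrainConfig(max_epochs=2, batch_size=8, seed=0)
        w1, _ = tq.train_stage(model, "segmentation", tiny_data, cfg)
        cfg2 = tq.TrainConfig(max_epochs=3, batch_size=8, seed=1, learning_rate=1e-2,
                              intensity_shift_range=0, lr_flip_prob=0)
        w2, _ = tq.train_stage(model, "classification", tiny_data, cfg2)
        merged = tq.merge_paths(w1, w2)

        x = tiny_data.images[:10]
        m_stage1 = build_model(tiny_model_cfg)
        m_stage1.network.load_state_dict(w1)
        m_stage2 = build_model(tiny_model_cfg)
        m_stage2.network.load_state_dict(w2)
        m_merged = build_model(tiny_model_cfg)
        m_merged.network.load_state_dict(merged)
        out_m = m_merged.forward(x)
        assert np.array_equal(out_m["seg"], m_stage1.forward(x)["seg"])
        assert np.array_equal(out_m["clf"], m_stage2.forward(x)["clf"])


class TestQuantizeModel:
    def test_batchnorm_folding_preserves_eval_outputs(self):
        from vesica.nn import Network

        r = np.random.default_rng(0)
        net = Network(outputs={})
        a = net.add("conv", Conv2D(2, 3, 3, 1, rng=r), ["input"], "backbone")
        bn = BatchNorm(3)
        bn.running_mean = r.normal(size=3).astype(np.float32)
        bn.running_var = r.uniform(0.5, 2.0, 3).astype(np.float32)
        bn.params["gamma"][...] = r.uniform(0.5, 1.5, 3)
        bn.params["beta"][...] = r.normal(size=3)
        net.outputs["out"] = net.add("bn", bn, [a], "backbone")
        x = r.random((2, 6, 6, 2), dtype=np.float32)
        before = net.forward(x)["out"]
        tq._fold_batchnorm(net)
        after = net.forward(x)["out"]
        assert np.allclose(before, after, atol=1e-5)

    def test_quantized_model_is_deterministic_and_close_to_float(self, tiny_data, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        cfg = tq.TrainConfig(max_epochs=3, batch_size=8, seed=0)
        tq.train_stage(model, "segmentation", tiny_data, cfg)
        qm = tq.quantize_model(model, tiny_data.images[:8][..., None])
        x = tiny_data.images[8:12]
        a = qm.forward(x)
        b = qm.forward(x)
        assert np.array_equal(a["seg"], b["seg"]) and np.array_equal(a["clf"], b["clf"])
        ref = model.forward(x)
        assert np.abs(a["seg"] - ref["seg"]).mean() < 0.1

    def test_save_load_round_trip(self, tiny_data, tiny_model_cfg, tmp_path):
        model = build_model(tiny_model_cfg)
        qm = tq.quantize_model(model, tiny_data.images[:8][..., None])
        qm.save(tmp_path / "q.npz")
        loaded = tq.QuantizedModel.from_file(tmp_path / "q.npz")
        x = tiny_data.images[:4]
        a, b = qm.forward(x), loaded.forward(x)
        assert np.allclose(a["seg"], b["seg"], atol=1e-6)
        assert np.allclose(a["clf"], b["clf"], atol=1e-6)

    def test_empty_calibration_rejected(self, tiny_model_cfg):
        model = build_model(tiny_model_cfg)
        with pytest.raises(InvalidArgumentError):
            tq.quantize_model(model, np.zeros((0, 32, 32, 1), np.float32))


def test_train_config_validation():
    with pytest.raises(InvalidArgumentError):
        tq.TrainConfig(alpha=1.5)
    with pytest.raises(InvalidArgumentError):
        tq.TrainConfig(patience=0)
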