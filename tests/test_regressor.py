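"""Stage-II pyramid attention regressor: attention math, variants, training."""

import numpy as np
import pytest

import mrfepi as m
from mrfepi import nn
from mrfepi.regressor import RegressorSpec, Stage2TrainConfig


class TestAttention:
    def test_hand_computed_two_position_single_head(self):
        attn = nn.MultiHeadSelfAttention(1, 1, rng=np.random.default_rng(0))
        attn.w_q.data[:] = 1
        attn.w_k.data[:] = 1
        attn.w_v.data[:] = 1
        attn.w_o.data[:] = 1
        x = np.array([[1.0], [2.0]], dtype=np.float32)  # l=2, d_ch=1
        out = m.multihead_attention(x, attn)
        # scores rows: softmax(1, 2) and softmax(2, 4); values (1, 2)
        w1 = np.exp([1.0, 2.0]) / np.exp([1.0, 2.0]).sum()
        w2 = np.exp([2.0, 4.0]) / np.exp([2.0, 4.0]).sum()
        expected = np.array([[w1 @ [1, 2]], [w2 @ [1, 2]]])
        np.testing.assert_allclose(out.numpy(), expected, rtol=1e-6)

    def test_single_position_identity_weights(self):
        h, d_s = 2, 3
        attn = nn.MultiHeadSelfAttention(h * d_s, h, rng=np.random.default_rng(1))
        for w in (attn.w_q, attn.w_k, attn.w_v):
            w.data[:] = np.stack([np.eye(d_s, dtype=np.float32)] * h)
        attn.w_o.data[:] = np.eye(h * d_s, dtype=np.float32)
        x = np.random.default_rng(2).normal(size=(1, h * d_s)).astype(np.float32)
        out = m.multihead_attention(x, attn)  # softmax over one position = 1
        np.testing.assert_allclose(out.numpy(), x, rtol=1e-6)

    def test_output_shape_contract(self):
        attn = nn.MultiHeadSelfAttention(128, 8, rng=np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(5, 19, 128)).astype(np.float32)
        assert m.multihead_attention(x, attn).shape == (5, 19, 128)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            nn.MultiHeadSelfAttention(10, 3)


class TestGammaResidual:
    def test_zero_gamma_bypasses_attention(self):
        x = np.array([1.0, 2.0])
        np.testing.assert_array_equal(m.gamma_residual(x, x * 9, 0.0), x)

    def test_pure_attention_limit(self):
        xa = np.array([3.0, 4.0])
        np.testing.assert_array_equal(m.gamma_residual(np.zeros(2), xa, 1.0), xa)

    def test_hand_value(self):
        assert m.gamma_residual(np.array([2.0]), np.array([4.0]), 0.5)[0] == 4.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.gamma_residual(np.zeros(2), np.zeros(3), 1.0)


class TestLoss:
    def test_identity_zero(self):
        assert m.stage2_loss(np.array([1000.0]), np.array([1000.0])) == 0.0

    def test_single_value_hand_case(self):
        # 10 + 100*0.01 = 11
        assert m.stage2_loss(np.array([1000.0]), np.array([990.0])) == pytest.approx(11.0)

    def test_two_value_hand_case(self):
        y = np.array([1000.0, 50.0])
        yp = np.array([1000.0, 45.0])
        # L1 = 2.5; MAPE term = 100 * 0.05 = 5
        assert m.stage2_loss(y, yp) == pytest.approx(7.5)

    def test_nonpositive_targets_rejected(self):
        with pytest.raises(ValueError):
            m.stage2_loss(np.array([0.0]), np.array([1.0]))


class TestArchitecture:
    def test_pyramid_scale_lengths(self):
        assert RegressorSpec().scale_lengths() == [19, 9, 3]

    @pytest.mark.parametrize("variant,n_out", [
        ("WPDaCNN", 2), ("PDCNN", 2), ("DCNN", 2), ("SCNN", 2),
    ])
    def test_forward_emits_two_finite_values(self, variant, n_out):
        model = m.build_regressor(RegressorSpec(variant=variant), seed=0)
        out = model.predict(np.random.default_rng(1).normal(size=35))
        assert out.shape == (n_out,)
        assert np.isfinite(out).all()

    def test_scnn_single_path_two_outputs(self):
        model = m.build_regressor(RegressorSpec(variant="SCNN"), seed=0)
        assert len(model.paths) == 1
        assert model.paths[0].fc_out.weight.shape == (3, 2)

    def test_attention_is_noop_at_init(self):
        """gamma_attn starts at 0, so attention weights cannot affect the output."""
        model = m.build_regressor(seed=5)
        x = np.random.default_rng(6).normal(size=(3, 35)).astype(np.float32)
        before = model.predict(x)
        rng = np.random.default_rng(7)
        for path in model.paths:
            for head in path.heads:
                head.attention.w_q.data[:] = rng.normal(size=head.attention.w_q.shape)
                head.attention.w_o.data[:] = rng.normal(size=head.attention.w_o.shape)
        np.testing.assert_array_equal(model.predict(x), before)

    def test_inference_bit_reproducible(self):
        model = m.build_regressor(seed=8)
        x = np.random.default_rng(9).normal(size=(4, 35)).astype(np.float32)
        np.testing.assert_array_equal(model.predict(x), model.predict(x))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            RegressorSpec(n_timepoints=20).scale_lengths()


@pytest.fixture(scope="module")
def tiny_training(small_dict):
    split = m.split_by_increment(small_dict, 2)
    cfg = Stage2TrainConfig(epochs=1, batch_size=64, seed=21)
    return small_dict, split, cfg


class TestTraining:
    def test_smoke_run_returns_curves(self, tiny_training):
        d, split, cfg = tiny_training
        model, curves = m.train_regressor(d, split, cfg=cfg)
        assert len(curves) == 1
        assert {"train_l1_ms", "train_mape_pct", "val_l1_ms", "val_mape_pct"} <= set(curves.columns)
        assert np.isfinite(curves.iloc[0]["val_loss"])

    def test_training_deterministic_under_seed(self, tiny_training):
        d, split, cfg = tiny_training
        _, curves_a = m.train_regressor(d, split, cfg=cfg)
        _, curves_b = m.train_regressor(d, split, cfg=cfg)
        assert curves_a.equals(curves_b)

    def test_empty_split_rejected(self, small_dict):
        empty = m.DictionarySplit(np.array([], dtype=int), np.arange(len(small_dict)))
        with pytest.raises(ValueError):
            m.train_regressor(small_dict, empty)


class TestPrediction:
    def test_masked_voxels_zero_and_units(self, small_dict):
        denoiser = m.build_denoiser(m.DenoiserSpec(depth_middle=1), seed=0)
        regressor = m.build_regressor(seed=1)
        data = np.zeros((3, 3, 35))
        mask = np.zeros((3, 3), bool)
        data[0, 0] = small_dict.signals[10]
        data[1, 1] = small_dict.signals[20]
        mask[0, 0] = mask[1, 1] = True
        stack = m.BaselineStack(data, mask)
        maps = m.predict_two_stage(denoiser, regressor, stack)
        assert maps.t1_map.shape == (3, 3)
        assert maps.t1_map[2, 2] == 0 and maps.t2s_map[0, 1] == 0
        assert maps.t1_map[0, 0] != 0

    def test_single_stage_skips_denoiser(self, small_dict):
        regressor = m.build_regressor(seed=2)
        data = small_dict.signals[5][None, None, :]
        stack = m.BaselineStack(data, np.ones((1, 1), bool))
        maps = m.predict_single_stage(regressor, stack)
        expected = regressor.predict(small_dict.signals[5:6].astype(np.float32))
        np.testing.assert_allclose(
            [maps.t1_map[0, 0], maps.t2s_map[0, 0]], expected[0], rtol=1e-6
        )
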