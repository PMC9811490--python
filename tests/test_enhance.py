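"""Progressive U-net: data preparation, loss, growth, fade-in, training."""

import numpy as np
import pytest

from hemipact.core import Volume
from hemipact.enhance import (
    TrainConfig,
    build_progressive_model,
    combined_loss,
    denormalize,
    desk_config,
    downsample_volume,
    enhance,
    load_model,
    normalize_pairs,
    save_model,
    train_progressive,
)
from hemipact.metrics import SSIMConfig, ssim3d
from hemipact.nn.autodiff import Tensor, upsample2_linear_array


def random_volumes(rng, n, edge=16):
    return [Volume(rng.random((edge, edge, edge))) for _ in range(n)]


class TestNormalization:
    def test_shifted_sets_normalize_identically(self, rng):
        a = random_volumes(rng, 3)
        b = [v.with_values(v.values * 2.0) for v in a]
        p1 = normalize_pairs(a, b)
        p2 = normalize_pairs([v.with_values(v.values + 5.0) for v in a], b)
        for q1, q2 in zip(p1, p2):
            np.testing.assert_allclose(q1.input.values, q2.input.values, atol=1e-12)

    def test_round_trip(self, rng):
        a = random_volumes(rng, 2)
        pairs = normalize_pairs(a, a)
        back = denormalize(pairs[0].input, pairs[0].input_bounds)
        np.testing.assert_allclose(back.values, a[0].values, atol=1e-12)

    def test_global_bounds_keep_dim_volumes_dim(self, rng):
        dim = Volume(0.1 * rng.random((8, 8, 8)))
        bright = Volume(1.0 + rng.random((8, 8, 8)))
        pairs = normalize_pairs([dim, bright], [dim, bright])
        assert pairs[0].input.values.max() < 0.1
        assert pairs[1].input.values.max() > 0.5

    def test_degenerate_range_rejected(self):
        flat = [Volume(np.ones((4, 4, 4)))]
        with pytest.raises(ValueError):
            normalize_pairs(flat, flat)


class TestDownsample:
    def test_block_mean_oracle(self, rng):
        v = Volume(rng.random((8, 8, 8)))
        d = downsample_volume(v, 4)
        ref = np.empty((4, 4, 4))
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    ref[i, j, k] = v.values[
                        2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2
                    ].mean()
        np.testing.assert_allclose(d.values, ref, atol=1e-12)
        assert d.voxel_mm == pytest.approx(2 * v.voxel_mm)

    def test_constant_preserved_and_factor_eight(self):
        v = Volume(np.full((32, 32, 32), 0.7))
        d = downsample_volume(v, 4)
        np.testing.assert_allclose(d.values, 0.7, atol=1e-15)

    def test_non_divisor_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample_volume(Volume(rng.random((8, 8, 8))), 3)


class TestCombinedLoss:
    def test_zero_at_identity(self, rng):
        x = rng.random((12, 12, 12))
        assert combined_loss(x, x, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_l1_only_limit(self, rng):
        x, y = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        assert combined_loss(x, y, 1.0) == pytest.approx(np.mean(np.abs(x - y)), abs=1e-12)

    def test_composition_matches_metrics_module(self, rng):
        x, y = rng.random((12, 12, 12)), rng.random((12, 12, 12))
        lam = 0.2
        cfg = SSIMConfig(window="gaussian", sigma=1.5, window_size=11, boundary="pad")
        expected = lam * np.mean(np.abs(x - y)) + (1 - lam) * (1 - ssim3d(x, y, cfg))
        assert combined_loss(x, y, lam) == pytest.approx(expected, abs=1e-9)

    def test_tensor_path_equals_plain_path(self, rng):
        x, y = rng.random((10, 10, 10)), rng.random((10, 10, 10))
        plain = combined_loss(x, y, 0.2)
        tensor = combined_loss(Tensor(x[None, None]), y[None, None], 0.2).item()
        assert tensor == pytest.approx(plain, abs=1e-9)

    def test_bounds_and_validation(self, rng):
        x, y = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        j = combined_loss(x, y, 0.2)
        assert 0.0 <= j <= 0.2 + 0.8 * 2.0
        with pytest.raises(ValueError):
            combined_loss(x, y, 1.5)


def tiny_config(**kw):
    base = dict(
        scales=(8, 16),
        batch_sizes=(4, 4),
        base_channels=4,
        channel_cap=8,
        epochs_per_stage=2,
        learning_rate=1e-3,
        seed=5,
    )
    base.update(kw)
    return TrainConfig(**base)


class TestProgressiveModel:
    def test_single_scale_is_plain_network(self, rng):
        cfg = tiny_config(scales=(8,), batch_sizes=(4,))
        model = build_progressive_model(cfg)
        assert model.n_subnetworks == 1
        out = model.predict(rng.random((8, 8, 8)).astype(np.float32))
        assert out.shape == (8, 8, 8)
        with pytest.raises(ValueError):
            model.grow()

    def test_four_scales_give_four_subnetworks(self):
        cfg = TrainConfig(base_channels=4, channel_cap=8)  # published 16..128 scales
        model = build_progressive_model(cfg)
        for _ in range(3):
            model.grow()
        assert model.n_subnetworks == 4

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(scales=(8, 24), batch_sizes=(4, 4))
        with pytest.raises(ValueError):
            TrainConfig(scales=(12,), batch_sizes=(4,))

    def test_growth_preserves_parameters_bit_exactly(self):
        model = build_progressive_model(tiny_config())
        before = model.state_dict()
        model.grow()
        after = model.state_dict()
        for name, value in before.items():
            assert np.array_equal(value, after[name]), name

    def test_fade_in_continuity_at_alpha_zero(self, rng):
        model = build_progressive_model(tiny_config())
        model.eval()
        x16 = rng.random((16, 16, 16)).astype(np.float32)
        x8 = downsample_volume(Volume(x16), 8).values.astype(np.float32)
        y_coarse = model.forward(Tensor(x8[None, None])).data[0, 0]
        model.grow()
        model.eval()
        model.fade_in_alpha = 0.0
        y_grown = model.forward(Tensor(x16[None, None])).data[0, 0]
        np.testing.assert_allclose(y_grown, upsample2_linear_array(y_coarse), atol=1e-6)


@pytest.fixture(scope="module")
def trained_tiny():
    rng = np.random.default_rng(17)
    # smooth input/target pairs with a deterministic relation to learn
    targets = []
    inputs = []
    from scipy.ndimage import gaussian_filter

    for _ in range(8):
        t = gaussian_filter(rng.random((16, 16, 16)), 1.5)
        targets.append(Volume(t))
        inputs.append(Volume(gaussian_filter(t, 1.0) + 0.02 * rng.standard_normal(t.shape)))
    pairs = normalize_pairs(inputs, targets)
    cfg = tiny_config(epochs_per_stage=4)
    model, history = train_progressive(pairs, cfg)
    return pairs, cfg, model, history


class TestTraining:
    def test_history_structure_and_alpha_ramp(self, trained_tiny):
        _, cfg, _, history = trained_tiny
        stages = sorted({h["stage"] for h in history})
        assert stages == [0, 1]
        alphas = [h["alpha"] for h in history if h["stage"] == 1]
        assert alphas[0] == 0.0
        assert alphas == sorted(alphas)
        assert alphas[-1] == 1.0

    def test_optimization_descends_within_each_stage(self, trained_tiny):
        # compare epochs at the same fade-in alpha: during the ramp the
        # objective's mixture changes, so only fixed-alpha epochs are
        # comparable
        _, _, _, history = trained_tiny
        for stage in (0, 1):
            steady = [h["train_loss"] for h in history if h["stage"] == stage and h["alpha"] == 1.0]
            assert len(steady) >= 2
            assert steady[-1] < steady[0]
        assert all(np.isfinite(h["val_loss"]) for h in history)

    def test_training_is_deterministic(self, trained_tiny):
        pairs, cfg, _, history = trained_tiny
        _, again = train_progressive(pairs, cfg)
        assert history == again

    def test_enhance_contract(self, trained_tiny, rng):
        pairs, _, model, _ = trained_tiny
        out1 = enhance(model, pairs[0].input)
        out2 = enhance(model, pairs[0].input)
        assert out1.shape == pairs[0].input.shape
        assert out1.values.min() >= 0.0 and out1.values.max() <= 1.0
        np.testing.assert_array_equal(out1.values, out2.values)
        with pytest.raises(ValueError):
            enhance(model, Volume(rng.random((8, 8, 8))))
        with pytest.raises(ValueError):
            enhance(model, Volume(5.0 * rng.random((16, 16, 16))))

    def test_checkpoint_round_trip(self, trained_tiny, tmp_path):
        pairs, _, model, _ = trained_tiny
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        a = enhance(model, pairs[1].input)
        b = enhance(loaded, pairs[1].input)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            train_progressive([], tiny_config())
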