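import numpy as np
import pytest

from bonesep.joint_model import (
    NetConfig,
    TileSpec,
    TrainConfig,
    build_unet,
    derive_joint_truth,
    dice_coefficient,
    extract_training_tiles,
    iou,
    load_checkpoint,
    predict_tiled,
    save_checkpoint,
    split_validation,
    train,
    validation_iou,
)
import bonesep.joint_model.nn as nn
from bonesep.volume_io import Volume3D
from oracles import joint_truth_reference


class TestDeriveJointTruth:
    def test_two_cubes_slab_centered_on_gap(self):
        labels = np.zeros((24, 30, 24), dtype=np.int32)
        labels[6:16, 4:14, 6:16] = 1
        labels[6:16, 16:26, 6:16] = 2  # 2-voxel gap at y in {14, 15}
        mask = derive_joint_truth(labels, dilation_size=5)
        want = joint_truth_reference(labels, 5)
        np.testing.assert_array_equal(mask, want)
        assert mask[10, 14, 10] and mask[10, 15, 10]  # gap is covered
        assert not mask[10, 4, 10]  # far side of bone 1 is not

    def test_single_label_empty_with_warning(self, caplog):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1
        with caplog.at_level("WARNING"):
            mask = derive_joint_truth(labels)
        assert not mask.any()
        assert "fewer than 2" in caplog.text

    def test_background_near_two_labels_always_included(self):
        labels = np.zeros((6, 7, 6), dtype=np.int32)
        labels[2, 2, 2] = 1
        labels[2, 4, 2] = 2
        mask = derive_joint_truth(labels, dilation_size=1)
        assert mask[2, 3, 2]  # within Chebyshev 1 of both

    @pytest.mark.parametrize("size", [1, 2, 3])
    def test_matches_chebyshev_oracle_random(self, rng, size):
        for _ in range(4):
            labels = np.zeros((14, 14, 14), dtype=np.int32)
            for lid in range(1, int(rng.integers(2, 6))):
                c = rng.integers(2, 12, size=3)
                r = int(rng.integers(1, 3))
                labels[
                    max(c[0] - r, 0) : c[0] + r,
                    max(c[1] - r, 0) : c[1] + r,
                    max(c[2] - r, 0) : c[2] + r,
                ] = lid
            got = derive_joint_truth(labels, dilation_size=size)
            want = joint_truth_reference(labels, size)
            np.testing.assert_array_equal(got, want)


class TestExtractTiles:
    def test_tile_shapes(self, default_phantom):
        joint = derive_joint_truth(default_phantom.truth, 5)
        tiles = extract_training_tiles(default_phantom.volume, joint, n_tiles=3, edge=48)
        assert len(tiles) == 3
        for img, m in tiles:
            assert img.shape == (48, 48, 48) and m.shape == (48, 48, 48)

    def test_small_volume_padded(self):
        vol = Volume3D(np.zeros((10, 10, 10)))
        tiles = extract_training_tiles(vol, np.zeros((10, 10, 10), bool), n_tiles=3, edge=32)
        assert tiles[0][0].shape == (32, 32, 32)

    def test_background_tile_emptier_than_cluster_tile(self, default_phantom):
        joint = derive_joint_truth(default_phantom.truth, 5)
        tiles = extract_training_tiles(default_phantom.volume, joint, n_tiles=3, edge=40)
        fg = [(img >= 2500).mean() for img, _ in tiles]
        assert fg[2] < fg[0]  # background tile < cluster tile

    def test_image_and_mask_aligned(self, default_phantom):
        joint = derive_joint_truth(default_phantom.truth, 5)
        tiles = extract_training_tiles(default_phantom.volume, joint, n_tiles=3, edge=40)
        for img, m in tiles:
            # bone voxels are never joint-truth interior: fraction of overlap
            # is bounded (sanity that both tiles come from the same window)
            assert img.shape == m.shape


class TestSplitValidation:
    def test_full_scale_counts_120_tiles(self):
        tiles = list(range(120))
        tr, va = split_validation(tiles, fraction=0.25, seed=0)
        assert len(va) == 30 and len(tr) == 90

    def test_rounding_8_tiles(self):
        tr, va = split_validation(list(range(8)), fraction=0.25, seed=1)
        assert len(va) == 2 and len(tr) == 6

    def test_deterministic_and_disjoint(self):
        tiles = list(range(20))
        tr1, va1 = split_validation(tiles, seed=7)
        tr2, va2 = split_validation(tiles, seed=7)
        assert tr1 == tr2 and va1 == va2
        assert set(tr1).isdisjoint(va1)
        assert sorted(tr1 + va1) == tiles

    def test_too_few_tiles_rejected(self):
        with pytest.raises(ValueError):
            split_validation([1, 2, 3])


class TestAutodiff:
    def test_conv_gradients_match_finite_differences(self, rng):
        x = rng.normal(size=(2, 6, 6, 6)).astype(np.float32)
        w = nn.Tensor(rng.normal(0, 0.4, size=(2, 2, 3, 3, 3)))
        b = nn.Tensor(rng.normal(size=2))
        g = nn.Tensor(rng.uniform(0.5, 1.5, 2))
        beta = nn.Tensor(rng.normal(size=2) * 0.1)
        target = (rng.random((2, 6, 6, 6)) > 0.5).astype(np.float32)

        def loss():
            # smooth graph (no relu): finite differences are trustworthy
            t = nn.Tensor(x)
            h = nn.channel_norm(nn.conv3d(t, w, b), g, beta)
            h = nn.up2(nn.down2(h))
            p = nn.sigmoid(h)
            return nn.dice_loss(p, target)

        L = loss()
        L.backward()
        # directional derivative along a random direction per parameter:
        # averages out float32 roundoff that plagues per-coordinate checks
        for p in (w, b, g, beta):
            saved = p.grad.copy()
            direction = rng.normal(size=p.data.shape).astype(np.float32)
            direction /= np.linalg.norm(direction)
            eps = 1e-2
            orig = p.data.copy()
            p.data = orig + eps * direction
            lp = float(loss().data)
            p.data = orig - eps * direction
            lm = float(loss().data)
            p.data = orig
            num = (lp - lm) / (2 * eps)
            analytic = float((saved * direction).sum())
            assert num == pytest.approx(analytic, rel=0.05, abs=2e-4)

    def test_relu_graph_gradient_direction(self, rng):
        # with relu kinks finite differences are only approximate; check the
        # directional derivative loosely
        x = rng.normal(size=(2, 6, 6, 6)).astype(np.float32)
        w = nn.Tensor(rng.normal(0, 0.4, size=(1, 2, 3, 3, 3)))
        b = nn.Tensor(rng.normal(size=1))
        target = (rng.random((1, 6, 6, 6)) > 0.5).astype(np.float32)

        def loss():
            p = nn.sigmoid(nn.relu(nn.conv3d(nn.Tensor(x), w, b)))
            return nn.dice_loss(p, target)

        L = loss()
        L.backward()
        saved = w.grad.copy()
        direction = rng.normal(size=w.data.shape).astype(np.float32)
        direction /= np.linalg.norm(direction)
        eps = 1e-2
        orig = w.data.copy()
        w.data = orig + eps * direction
        lp = float(loss().data)
        w.data = orig - eps * direction
        lm = float(loss().data)
        w.data = orig
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(float((saved * direction).sum()), rel=0.2, abs=1e-3)

    def test_dice_and_iou_set_arithmetic(self):
        pred = np.zeros((4, 4, 4))
        truth = np.zeros((4, 4, 4))
        pred[:2] = 1.0
        truth[1:3] = 1.0  # |P|=32, |T|=32, |P∩T|=16, |P∪T|=48
        assert dice_coefficient(pred, truth, eps=0) == pytest.approx(2 * 16 / 64, abs=1e-6)
        assert iou(pred > 0, truth > 0) == pytest.approx(16 / 48, abs=1e-6)

    def test_iou_extremes(self):
        truth = np.zeros((3, 3, 3), bool)
        truth[1] = True
        assert iou(truth, truth) == 1.0
        assert iou(np.zeros_like(truth), truth) == 0.0

    def test_dice_loss_value(self):
        pred = nn.Tensor(np.ones((2, 2, 2)))
        target = np.ones((2, 2, 2))
        assert float(nn.dice_loss(pred, target, eps=0).data) == pytest.approx(0.0)


class TestUNet:
    def test_forward_shape_and_range(self):
        model = build_unet(NetConfig(base_channels=2, depth=3, patch=16))
        out = model.forward(np.zeros((1, 16, 16, 16), dtype=np.float32))
        assert out.shape == (1, 16, 16, 16)
        assert 0.0 <= out.data.min() <= out.data.max() <= 1.0

    def test_zero_input_finite_output(self):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8))
        out = model.predict(np.zeros((1, 8, 8, 8), dtype=np.float32))
        assert np.isfinite(out).all()

    def test_same_seed_identical_weights(self):
        a = build_unet(NetConfig(base_channels=3, depth=2, patch=8, seed=11))
        b = build_unet(NetConfig(base_channels=3, depth=2, patch=8, seed=11))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_patch_depth_incompatibility_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(base_channels=2, depth=4, patch=12)

    def test_predict_matches_taped_forward(self, rng):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8))
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(model.predict(x), model.forward(x).data, atol=1e-6)

    def test_parameter_count_reported(self):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8))
        assert model.n_parameters() == sum(p.data.size for p in model.parameters())

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8, seed=3))
        for p in model.parameters():
            p.data += rng.normal(size=p.data.shape).astype(np.float32)
        save_checkpoint(model, tmp_path / "m.npz", extra={"note": "test"})
        back = load_checkpoint(tmp_path / "m.npz")
        assert back.cfg == model.cfg
        for k in model.params:
            np.testing.assert_array_equal(back.params[k].data, model.params[k].data)


class TestTraining:
    @staticmethod
    def _toy_tiles(rng, n=2, edge=16):
        tiles = []
        for _ in range(n):
            img = rng.uniform(0, 8000, size=(edge, edge, edge))
            mask = np.zeros((edge, edge, edge), dtype=bool)
            mask[:, edge // 2 - 2 : edge // 2 + 2, :] = True
            img[mask] = 0.0
            tiles.append((img, mask))
        return tiles

    def test_lr_zero_leaves_weights_unchanged(self, rng):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8, seed=0))
        before = model.state_dict()
        tiles = self._toy_tiles(rng)
        train(model, tiles, None, TrainConfig(epochs=1, lr=0.0, patches_per_epoch=2, patch=8))
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_loss_decreases_on_toy_task(self, rng):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8, seed=0))
        tiles = self._toy_tiles(rng)
        _, hist = train(
            model, tiles, None, TrainConfig(epochs=30, lr=3e-3, patches_per_epoch=2, patch=8)
        )
        assert hist.train_dice_loss.iloc[-5:].mean() < hist.train_dice_loss.iloc[:5].mean()

    def test_validation_iou_perfect_and_empty(self):
        class Oracle:
            cfg = NetConfig(base_channels=1, depth=1, patch=8)

            def normalize(self, v):
                return np.asarray(v, dtype=np.float32)[None]

            def predict(self, x):
                return (x < 1000).astype(np.float32)

        tiles = [(np.where(np.arange(8 * 8 * 8).reshape(8, 8, 8) % 2 == 0, 0.0, 5000.0),
                  np.arange(8 * 8 * 8).reshape(8, 8, 8) % 2 == 0)]
        assert validation_iou(Oracle(), tiles) == 1.0

        class Never:
            cfg = NetConfig(base_channels=1, depth=1, patch=8)

            def normalize(self, v):
                return np.asarray(v, dtype=np.float32)[None]

            def predict(self, x):
                return np.zeros_like(x)

        assert validation_iou(Never(), tiles) == 0.0

    def test_empty_training_set_rejected(self):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], None, TrainConfig(epochs=1))

    def test_all_empty_masks_warns(self, rng, caplog):
        model = build_unet(NetConfig(base_channels=2, depth=2, patch=8, seed=0))
        tiles = [(rng.uniform(0, 8000, (8, 8, 8)), np.zeros((8, 8, 8), bool))]
        with caplog.at_level("WARNING"):
            train(model, tiles, None, TrainConfig(epochs=1, patches_per_epoch=1, patch=8))
        assert "empty joint masks" in caplog.text


class TestPredictTiled:
    def test_output_shape_and_tile_count(self, rng):
        model = build_unet(NetConfig(base_channels=1, depth=2, patch=8, seed=0))
        vol = rng.uniform(0, 8000, size=(20, 20, 20))
        pred = predict_tiled(model, vol, TileSpec(tile_edge=16, overlap=0))
        assert pred.probability.shape == (20, 20, 20)
        assert pred.mask.dtype == bool

    def test_constant_volume_constant_output(self, rng):
        # seam-free stitching: a constant input must give a constant output
        model = build_unet(NetConfig(base_channels=1, depth=2, patch=8, seed=0))
        vol = np.full((20, 20, 20), 4000.0)
        pred = predict_tiled(model, vol, TileSpec(tile_edge=16))
        assert pred.probability.max() - pred.probability.min() < 1e-6

    def test_probability_in_unit_interval(self, rng):
        model = build_unet(NetConfig(base_channels=1, depth=2, patch=8, seed=0))
        vol = rng.uniform(0, 8000, size=(12, 12, 12))
        pred = predict_tiled(model, vol, TileSpec(tile_edge=8))
        assert pred.probability.min() >= 0.0 and pred.probability.max() <= 1.0

    def test_indivisible_tile_edge_rejected(self):
        model = build_unet(NetConfig(base_channels=1, depth=3, patch=8, seed=0))
        with pytest.raises(ValueError, match="divisible"):
            predict_tiled(model, np.zeros((8, 8, 8)), TileSpec(tile_edge=10))

    def test_tile_spec_validated(self):
        with pytest.raises(ValueError):
            TileSpec(tile_edge=8, overlap=8)
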