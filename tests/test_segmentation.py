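import numpy as np
import pytest

from cervimetry.io import ImageVolume
from cervimetry.phantom import (
    IntensityModel,
    PhantomSpec,
    generate_phantom,
    render_intensity,
)
from cervimetry.segmentation import (
    AugmentationConfig,
    UNet3D,
    UNetConfig,
    histogram_match,
    predict_segmentation,
    preprocess,
    train_segmentation,
    _backproject_labels,
    _resample_labels_to,
)


def _small_pairs(n, grid=32, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        spec = PhantomSpec(
            inlet_point=(0, 0, 8), mid_point=(0, 0, 0), outlet_point=(0, 0, -8),
            canal_radius=2.5, inner_thickness=1.5, outer_thickness=2.0,
            grid_size=grid, spacing=1.0, supersampling=2,
        )
        vol, _ = generate_phantom(spec)
        img = render_intensity(vol, IntensityModel(seed=int(rng.integers(2**31))))
        pairs.append((img, vol))
    return pairs


class TestConfig:
    def test_grid_divisibility_enforced(self):
        with pytest.raises(ValueError):
            UNetConfig(channels=(4, 8, 16), grid=34)

    def test_parameter_count_matches_hand_count_depth2(self):
        """Analytic parameter count for the depth-2 architecture."""
        cfg = UNetConfig(channels=(4, 8), grid=16, num_classes=6)
        net = UNet3D(cfg)

        def conv_params(cin, cout, k=3):
            return cout * cin * k**3 + cout

        def bn_params(c):
            return 2 * c

        expected = (
            # encoder level 1: conv(1->4), conv(4->4), 2 BN
            conv_params(1, 4) + conv_params(4, 4) + 2 * bn_params(4)
            # encoder level 2 (bottleneck): conv(4->8), conv(8->8), 2 BN
            + conv_params(4, 8) + conv_params(8, 8) + 2 * bn_params(8)
            # decoder: upsample conv(8->4), block conv(8->4)+conv(4->4), 2 BN
            + conv_params(8, 4) + conv_params(8, 4) + conv_params(4, 4)
            + 2 * bn_params(4)
            # output 1x1x1 conv(4->6)
            + conv_params(4, 6, k=1)
        )
        assert net.num_params() == expected

    def test_full_scale_recipe_is_expressible(self):
        cfg = UNetConfig(channels=(32, 64, 128, 256, 512), grid=128)
        assert cfg.depth == 5
        assert cfg.grid % 2 ** (cfg.depth - 1) == 0

    def test_rotation_limit_capped(self):
        with pytest.raises(ValueError):
            AugmentationConfig(rotation_limit_deg=60.0)


class TestPreprocess:
    def test_isotropic_identity_geometry(self):
        affine = np.eye(4)
        affine[:3, 3] = -15.5
        img = ImageVolume(voxels=np.random.default_rng(0).random((32, 32, 32)), affine=affine)
        x, mapping = preprocess(img, 32)
        assert x.shape == (1, 32, 32, 32)
        assert np.allclose(mapping.affine, affine, atol=1e-9)
        assert x.min() == pytest.approx(0.0) and x.max() == pytest.approx(1.0)

    def test_small_volume_centred_with_padding(self):
        img = ImageVolume(voxels=np.ones((16, 16, 16)), affine=np.eye(4))
        x, mapping = preprocess(img, 32)
        assert x.shape == (1, 32, 32, 32)
        # world centre preserved
        old_centre = img.voxel_to_world(np.array([7.5, 7.5, 7.5]))
        new_centre = mapping.affine[:3, :3] @ np.array([15.5] * 3) + mapping.affine[:3, 3]
        assert np.allclose(old_centre, new_centre, atol=1e-6)

    def test_anisotropic_round_trip_within_one_voxel(self):
        affine = np.diag([1.0, 1.0, 2.0, 1.0])
        vox = np.zeros((24, 24, 12), dtype=np.int16)
        vox[8:16, 8:16, 4:8] = 1
        from cervimetry.io import LabelVolume

        lab = LabelVolume(voxels=vox, affine=affine)
        img = ImageVolume(voxels=vox.astype(float), affine=affine)
        x, mapping = preprocess(img, 32)
        y = _resample_labels_to(lab, mapping)
        back = _backproject_labels(y, mapping, img)
        # centroid of the blob survives the round trip to within one voxel
        c0 = np.argwhere(vox == 1).mean(0)
        c1 = np.argwhere(back.voxels == 1).mean(0)
        assert np.all(np.abs(c0 - c1) <= 1.0)


class TestTraining:
    def test_loss_decreases(self):
        pairs = _small_pairs(3)
        cfg = UNetConfig(channels=(2, 4), grid=32, iterations=60, seed=0,
                         lr_init=1e-2, dropout=0.0)
        model = train_segmentation(pairs, cfg, AugmentationConfig(seed=0, probability=0.0))
        assert np.mean(model.loss_trajectory[-10:]) < model.loss_trajectory[0]

    def test_same_seed_reproduces_trajectory(self):
        pairs = _small_pairs(2)
        cfg = UNetConfig(channels=(2, 4), grid=32, iterations=25, seed=3)
        m1 = train_segmentation(pairs, cfg, AugmentationConfig(seed=3))
        m2 = train_segmentation(pairs, cfg, AugmentationConfig(seed=3))
        assert m1.loss_trajectory == m2.loss_trajectory

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_segmentation(_small_pairs(1), UNetConfig(channels=(2, 4), grid=32))


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        pairs = _small_pairs(4, seed=1)
        cfg = UNetConfig(channels=(3, 6), grid=32, iterations=150, seed=0,
                         lr_init=1e-2)
        return pairs, train_segmentation(pairs, cfg, AugmentationConfig(seed=0))

    def test_prediction_is_valid_label_volume(self, trained):
        pairs, model = trained
        pred = predict_segmentation(model, pairs[0][0])
        assert pred.shape == pairs[0][0].shape
        assert set(np.unique(pred.voxels)) <= set(range(6))

    def test_prediction_deterministic(self, trained):
        pairs, model = trained
        a = predict_segmentation(model, pairs[0][0])
        b = predict_segmentation(model, pairs[0][0])
        assert np.array_equal(a.voxels, b.voxels)

    def test_all_zero_image_does_not_crash(self, trained):
        _, model = trained
        img = ImageVolume(voxels=np.zeros((32, 32, 32)), affine=np.eye(4))
        pred = predict_segmentation(model, img)
        assert set(np.unique(pred.voxels)) <= set(range(6))


def test_histogram_match_maps_quantiles():
    rng = np.random.default_rng(0)
    img = rng.random((16, 16, 16)).astype(np.float32)
    ref = (rng.random((16, 16, 16)) * 3 + 2).astype(np.float32)
    out = histogram_match(img, ref)
    assert np.quantile(out, 0.5) == pytest.approx(np.quantile(ref, 0.5), abs=0.1)
    # monotone transform preserves ordering
    flat_in, flat_out = img.ravel(), out.ravel()
    order = np.argsort(flat_in)
    assert np.all(np.diff(flat_out[order]) >= -1e-6)
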