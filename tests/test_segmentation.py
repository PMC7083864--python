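import numpy as np
import pytest

from astroseg.filters import build_filter_bank
from astroseg.nn import ConstrainedConv2d, Conv2d, UNet
from astroseg.segmentation import (GESUNetSpec, TrainingSet, augment,
                                   basis_from_bank, build_gesunet,
                                   constrained_conv_layer, desk_spec,
                                   load_model, paper_spec, rigid_transform,
                                   save_model, segment_patch, train)


@pytest.fixture(scope="module")
def tiny_spec():
    return GESUNetSpec(patch_size=16, depth=2, base_channels=4,
                       n_basis=5, basis_kernel_size=5)


@pytest.fixture(scope="module")
def tiny_model(tiny_spec):
    return build_gesunet(tiny_spec, seed=0)


def random_training_set(n, size, rng):
    pairs = []
    for _ in range(n):
        img = rng.random((size, size))
        mask = np.zeros((size, size), dtype=np.uint8)
        r, c = rng.integers(2, size - 4, size=2)
        mask[r:r + 4, c:c + 4] = 1
        img = np.clip(img * 0.2 + mask * 0.7, 0, 1)
        pairs.append((img, mask))
    return TrainingSet(patches=pairs)


class TestConstrainedConvLayer:
    def test_one_hot_equals_plain_convolution(self, rng):
        bank = build_filter_bank(n_scales=1, n_orientations=4,
                                 base_kernel_size=5)
        basis = basis_from_bank(bank)
        x = rng.random((1, 1, 12, 12)).astype(np.float32)
        for b in range(basis.shape[0]):
            coeff = np.zeros((1, 1, basis.shape[0]), dtype=np.float32)
            coeff[0, 0, b] = 1.0
            out = constrained_conv_layer(x, coeff, basis)
            conv = Conv2d(1, 1, 5)
            conv.params["w"] = basis[b][None, None]
            conv.params["b"] = np.zeros(1, dtype=np.float32)
            np.testing.assert_allclose(out, conv.forward(x), atol=1e-6)

    def test_random_coefficients_match_basis_sum_oracle(self, rng):
        # independent oracle: sum of separate per-basis convolutions
        basis = rng.standard_normal((6, 5, 5)).astype(np.float32)
        coeff = rng.standard_normal((3, 2, 6)).astype(np.float32)
        x = rng.random((2, 2, 8, 8)).astype(np.float32)
        out = constrained_conv_layer(x, coeff, basis)
        expected = np.zeros_like(out)
        for b in range(6):
            conv = Conv2d(2, 3, 5)
            w = np.zeros((3, 2, 5, 5), dtype=np.float32)
            for o in range(3):
                for i in range(2):
                    w[o, i] = coeff[o, i, b] * basis[b]
            conv.params["w"] = w
            conv.params["b"] = np.zeros(3, dtype=np.float32)
            expected += conv.forward(x)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_parameter_count_independent_of_kernel_size(self, rng):
        basis15 = rng.standard_normal((9, 15, 15)).astype(np.float32)
        layer = ConstrainedConv2d(1, 16, basis15)
        n_trainable = sum(v.size for v in layer.params.values())
        assert layer.params["coeff"].size == 16 * 1 * 9 == 144
        assert n_trainable == 144 + 16
        free = Conv2d(1, 16, 15)
        assert free.params["w"].size == 16 * 1 * 15 * 15 == 3600

    def test_shape_mismatch_raises(self, rng):
        basis = rng.standard_normal((4, 5, 5)).astype(np.float32)
        coeff = rng.standard_normal((2, 1, 7)).astype(np.float32)
        with pytest.raises(ValueError):
            constrained_conv_layer(np.zeros((1, 1, 8, 8)), coeff, basis)


class TestBuildGesunet:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GESUNetSpec(patch_size=100, depth=3)
        with pytest.raises(ValueError):
            GESUNetSpec(n_basis=1)
        with pytest.raises(ValueError):
            GESUNetSpec(loss="mse")

    def test_forward_zeros_finite_in_unit_interval(self, tiny_model):
        y = tiny_model.forward(np.zeros((1, 1, 16, 16), dtype=np.float32))
        assert y.shape == (1, 1, 16, 16)
        assert np.all(np.isfinite(y))
        assert y.min() >= 0.0 and y.max() <= 1.0

    @pytest.mark.parametrize("size", [64, 128])
    def test_output_shape_matches_input(self, size):
        spec = GESUNetSpec(patch_size=size, depth=3, base_channels=2,
                           n_basis=3, basis_kernel_size=5)
        model = build_gesunet(spec, seed=1)
        y = model.forward(np.zeros((1, 1, size, size), dtype=np.float32))
        assert y.shape == (1, 1, size, size)

    def test_constrained_encoder_has_fewer_parameters(self):
        spec = desk_spec()
        constrained = build_gesunet(spec, seed=0).unet1
        free = UNet(in_channels=1, depth=spec.depth,
                    base_channels=spec.base_channels,
                    kernel_size=spec.basis_kernel_size, basis=None,
                    rng=np.random.default_rng(0))
        assert constrained.parameter_count() < free.parameter_count()

    def test_encoder_layers_are_constrained(self, tiny_model):
        for block in tiny_model.unet1.enc_blocks:
            convs = [l for l in block if l.params]
            assert all(isinstance(l, ConstrainedConv2d) for l in convs)
        for block in tiny_model.unet2.enc_blocks:
            convs = [l for l in block if l.params]
            assert all(isinstance(l, Conv2d) for l in convs)

    def test_overfit_five_pairs(self, rng):
        # loss must drop and reach small MAE when memorizing 5 samples
        spec = GESUNetSpec(patch_size=32, depth=3, base_channels=8,
                           n_basis=9, basis_kernel_size=5)
        model = build_gesunet(spec, seed=3)
        ts = random_training_set(5, 32, rng)
        # batch == set size, so one optimizer step per epoch: 200 steps
        history = train(model, ts, epochs=200, validation_fraction=0.0,
                        seed=0, batch_size=5)
        assert history.train_mae[-1] < 0.05
        assert history.train_mae[-1] < history.train_mae[0]

    def test_pretrained_transfer_requires_local_file(self):
        spec = GESUNetSpec(patch_size=16, depth=2, base_channels=4,
                           n_basis=5, basis_kernel_size=5,
                           transfer_encoder="/nonexistent/weights.npz")
        with pytest.raises(ValueError, match="no download"):
            build_gesunet(spec, seed=0)

    def test_transfer_from_npz(self, tmp_path, tiny_spec, rng):
        donor = build_gesunet(tiny_spec, seed=7)
        arrays = {}
        for i, block in enumerate(donor.unet2.enc_blocks):
            convs = [l for l in block if l.params]
            for j, conv in enumerate(convs):
                arrays[f"enc{i}_conv{j}_w"] = conv.params["w"]
                arrays[f"enc{i}_conv{j}_b"] = conv.params["b"]
        path = tmp_path / "enc.npz"
        np.savez(path, **arrays)
        spec = GESUNetSpec(patch_size=16, depth=2, base_channels=4,
                           n_basis=5, basis_kernel_size=5,
                           transfer_encoder=str(path))
        model = build_gesunet(spec, seed=0)
        got = [l for l in model.unet2.enc_blocks[0] if l.params][0]
        want = [l for l in donor.unet2.enc_blocks[0] if l.params][0]
        np.testing.assert_array_equal(got.params["w"], want.params["w"])


class TestAugment:
    def test_published_augmentation_count(self):
        rng = np.random.default_rng(0)
        pairs = [(rng.random((8, 8)), np.zeros((8, 8), dtype=np.uint8))
                 for _ in range(118)]
        ts = TrainingSet(patches=pairs)
        out = augment(ts, k=20, seed=0)
        assert len(out) == 2478

    def test_k_zero_is_identity(self, rng):
        ts = random_training_set(4, 16, rng)
        out = augment(ts, k=0, seed=0)
        assert len(out) == 4
        for (a, am), (b, bm) in zip(ts.patches, out.patches):
            np.testing.assert_array_equal(a, b)
            np.testing.assert_array_equal(am, bm)

    def test_deterministic_given_seed(self, rng):
        ts = random_training_set(3, 16, rng)
        o1 = augment(ts, k=2, seed=5)
        o2 = augment(ts, k=2, seed=5)
        for (a, am), (b, bm) in zip(o1.patches, o2.patches):
            np.testing.assert_array_equal(a, b)
            np.testing.assert_array_equal(am, bm)

    def test_right_angle_rotation_preserves_mask_area(self, rng):
        ts = random_training_set(1, 16, rng)
        img, mask = ts.patches[0]
        img_t, mask_t = rigid_transform(img, mask, 90.0, (0, 0))
        assert mask_t.sum() == mask.sum()

    def test_image_and_mask_transformed_jointly(self, rng):
        img = np.zeros((16, 16))
        img[4:8, 4:8] = 1.0
        mask = (img > 0).astype(np.uint8)
        img_t, mask_t = rigid_transform(img, mask, 37.0, (2, -1))
        # foreground of the transformed image stays under the mask
        assert (img_t[mask_t == 1] > 0.2).mean() > 0.8

    def test_negative_k_raises(self, rng):
        with pytest.raises(ValueError):
            augment(random_training_set(1, 8, rng), k=-1)


class TestTrainAndSegment:
    def test_empty_training_set_raises(self, tiny_model):
        with pytest.raises(ValueError):
            train(tiny_model, TrainingSet(patches=[]), epochs=1)

    def test_zero_validation_fraction_empty_history(self, rng, tiny_spec):
        model = build_gesunet(tiny_spec, seed=0)
        ts = random_training_set(4, 16, rng)
        history = train(model, ts, epochs=2, validation_fraction=0.0, seed=0)
        assert history.val_mae == []
        assert len(history.train_mae) == 2

    def test_training_reduces_loss(self, rng, tiny_spec):
        model = build_gesunet(tiny_spec, seed=0)
        ts = random_training_set(20, 16, rng)
        history = train(model, ts, epochs=10, validation_fraction=0.2, seed=0)
        assert history.train_mae[-1] < history.train_mae[0]
        assert len(history.val_mae) == len(history.train_mae)

    def test_reproducible_given_seed(self, rng, tiny_spec):
        ts = random_training_set(6, 16, rng)
        h1 = train(build_gesunet(tiny_spec, seed=2), ts, epochs=3, seed=9)
        h2 = train(build_gesunet(tiny_spec, seed=2), ts, epochs=3, seed=9)
        assert h1.train_mae == h2.train_mae

    def test_segment_patch_threshold_zero_all_ones(self, tiny_model):
        mask = segment_patch(tiny_model, np.zeros((16, 16)), prob_threshold=0.0)
        assert mask.all()

    def test_segment_patch_deterministic_on_zeros(self, tiny_model):
        a = segment_patch(tiny_model, np.zeros((16, 16)))
        b = segment_patch(tiny_model, np.zeros((16, 16)))
        np.testing.assert_array_equal(a, b)

    def test_segment_patch_shape_mismatch(self, tiny_model):
        with pytest.raises(ValueError):
            segment_patch(tiny_model, np.zeros((8, 8)))

    def test_save_load_roundtrip(self, tmp_path, tiny_spec, rng):
        model = build_gesunet(tiny_spec, seed=4)
        x = rng.random((16, 16)).astype(np.float32)
        path = tmp_path / "model.npz"
        save_model(model, str(path))
        loaded = load_model(str(path))
        np.testing.assert_allclose(
            model.forward(x[None, None]), loaded.forward(x[None, None]),
            atol=1e-7)
        assert loaded.spec == tiny_spec


class TestAblationHarness:
    def test_histories_for_all_three_variants(self, rng):
        from astroseg.segmentation import ablation_histories

        spec = GESUNetSpec(patch_size=32, depth=3, base_channels=8,
                           n_basis=9, basis_kernel_size=5)
        ts = random_training_set(6, 32, rng)
        out = ablation_histories(ts, spec, epochs=2, seed=0,
                                 validation_fraction=0.0)
        assert set(out) == {"stacked", "constrained_only", "free_only"}
        for history in out.values():
            assert len(history.train_mae) == 2
            assert all(np.isfinite(v) for v in history.train_mae)


class TestSpecs:
    def test_presets(self):
        assert paper_spec().patch_size == 128
        assert paper_spec().depth == 4
        assert desk_spec().patch_size == 64
        assert desk_spec().depth == 3
        assert desk_spec().base_channels == 8

    def test_training_set_validation(self, rng):
        with pytest.raises(ValueError):
            TrainingSet(patches=[(np.zeros((4, 4)), np.zeros((5, 5)))])
        with pytest.raises(ValueError):
            TrainingSet(patches=[(np.zeros((4, 4)), np.full((4, 4), 2))])
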