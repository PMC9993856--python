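import numpy as np
import pytest

from sctdir.core import ImageGrid
from sctdir.nn import PatchDiscriminator, Tensor
from sctdir.phantom import ArtifactConfig, PhantomConfig, degrade_to_cbct, generate_phantom, stack_slices
from sctdir.translation import (
    FeatureStack,
    GeneratorSpec,
    LossConfig,
    TrainConfig,
    TranslationModel,
    _nce_from_pairs,
    denormalize_intensities,
    encode_and_project,
    gan_loss,
    lr_schedule,
    multilayer_patchnce,
    normalize_intensities,
    patch_nce_loss,
    total_loss,
    train_translation,
    translate,
)


@pytest.fixture(scope="module")
def tiny_model():
    spec = GeneratorSpec(base_channels=4, n_res_blocks=1, n_down=2, tap_layers=(0, 1, 2))
    return TranslationModel(spec, LossConfig(patches_per_layer=8), seed=0)


@pytest.fixture(scope="module")
def tiny_image():
    img, _ = generate_phantom(PhantomConfig(shape=(32, 32), spacing=(2.0, 2.0), seed=1))
    return img


class TestPatchNceLoss:
    def test_uniform_logits_log_n_plus_one(self):
        # v.v+ == v.v-_n for all n  ->  loss = log(N+1)
        v = np.array([1.0, 0.0])
        pos = np.array([0.0, 1.0])
        for n in (1, 3, 10):
            negs = np.tile(pos, (n, 1))
            assert patch_nce_loss(v, pos, negs, 0.07) == pytest.approx(np.log(n + 1), rel=1e-12)

    def test_n1_uniform_is_log2(self):
        v = np.array([1.0, 0.0])
        assert patch_nce_loss(v, v, v[None], 0.07) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_orthogonal_negative_closed_form(self):
        # v=(1,0)=v+, v-=(0,1), tau=0.07: loss = log(1 + e^(-1/0.07)) ~ 6.2e-7
        v = np.array([1.0, 0.0])
        neg = np.array([[0.0, 1.0]])
        expected = np.log1p(np.exp(-1.0 / 0.07))
        got = patch_nce_loss(v, v, neg, 0.07)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(6.2e-7, rel=0.01)

    def test_matches_softmax_cross_entropy_oracle(self, rng):
        # direct softmax cross-entropy evaluation on random unit vectors
        for _ in range(20):
            k, n = 8, 5
            vecs = rng.standard_normal((n + 2, k))
            vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
            v, pos, negs = vecs[0], vecs[1], vecs[2:]
            logits = np.concatenate([[v @ pos], negs @ v]) / 0.07
            oracle = -np.log(np.exp(logits[0]) / np.exp(logits).sum())
            assert patch_nce_loss(v, pos, negs, 0.07) == pytest.approx(oracle, abs=1e-6)

    def test_strictly_positive(self, rng):
        vecs = rng.standard_normal((4, 6))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        assert patch_nce_loss(vecs[0], vecs[1], vecs[2:], 0.07) > 0

    def test_monotone_in_similarities(self):
        # decreasing in v.v+; increasing in v.v-
        def loss_at(p, n):
            logits = np.array([p, n]) / 0.07
            return float(np.log(np.exp(logits).sum()) - logits[0])

        assert loss_at(0.9, 0.1) < loss_at(0.8, 0.1)
        assert loss_at(0.5, 0.3) < loss_at(0.5, 0.4)

    def test_stable_at_temperature_extremes(self):
        # logits up to +-1/tau with tau=0.07 (~14.3) stay finite
        v = np.array([1.0, 0.0])
        neg = np.array([[-1.0, 0.0]])
        val = patch_nce_loss(v, v, neg, 0.07)
        assert np.isfinite(val)

    def test_invalid_temperature(self):
        v = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            patch_nce_loss(v, v, v[None], 0.0)

    def test_default_temperature_config(self):
        assert LossConfig().temperature == 0.07


class TestEncodeAndProject:
    def test_unit_norm(self, tiny_model, tiny_image):
        locs = [np.arange(8)] * 3
        stack = encode_and_project(tiny_image, tiny_model, locs)
        for vecs in stack.vectors:
            np.testing.assert_allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-5)

    def test_deterministic_under_fixed_weights(self, tiny_model, tiny_image):
        locs = [np.arange(8)] * 3
        a = encode_and_project(tiny_image, tiny_model, locs)
        b = encode_and_project(tiny_image, tiny_model, locs)
        for va, vb in zip(a.vectors, b.vectors):
            np.testing.assert_array_equal(va, vb)

    def test_vector_count(self, tiny_model, tiny_image):
        # S_l = 8 locations on L = 3 layers -> 24 vectors
        locs = [np.arange(8)] * 3
        stack = encode_and_project(tiny_image, tiny_model, locs)
        assert stack.n_vectors() == 24

    def test_out_of_range_location(self, tiny_model, tiny_image):
        locs = [np.array([10**9])] * 3
        with pytest.raises(IndexError):
            encode_and_project(tiny_image, tiny_model, locs)


class TestMultilayerPatchnce:
    def test_identical_features_give_log_s(self):
        # all projected features identical -> per-location uniform logits
        s, k = 6, 4
        z = np.tile(np.eye(k)[0], (s, 1))
        loss = _nce_from_pairs(Tensor(z), Tensor(z), 0.07)
        assert loss.item() == pytest.approx(np.log(s), rel=1e-5)

    def test_permutation_invariance(self, rng):
        s, k = 10, 8
        z_q = rng.standard_normal((s, k))
        z_k = rng.standard_normal((s, k))
        z_q /= np.linalg.norm(z_q, axis=1, keepdims=True)
        z_k /= np.linalg.norm(z_k, axis=1, keepdims=True)
        base = _nce_from_pairs(Tensor(z_q), Tensor(z_k), 0.07).item()
        perm = rng.permutation(s)
        permuted = _nce_from_pairs(Tensor(z_q[perm]), Tensor(z_k[perm]), 0.07).item()
        assert permuted == pytest.approx(base, rel=1e-5)

    def test_finite_on_phantom(self, tiny_model, tiny_image):
        val = multilayer_patchnce(tiny_model, [tiny_image], seed=0)
        assert np.isfinite(val) and val > 0

    def test_requires_two_patches(self):
        with pytest.raises(ValueError):
            LossConfig(patches_per_layer=1)


class TestGanLoss:
    def test_uninformative_discriminator(self):
        assert gan_loss(np.full(4, 0.5), np.full(4, 0.5)) == pytest.approx(2 * np.log(0.5))

    def test_perfect_discriminator_limit(self):
        val = gan_loss(np.full(4, 1 - 1e-9), np.full(4, 1e-9))
        assert -1e-6 < val < 0

    def test_monotone_in_d_real(self):
        # finite-difference scan: increasing D(real) increases the loss
        fake = np.full(3, 0.4)
        vals = [gan_loss(np.full(3, p), fake) for p in (0.2, 0.4, 0.6, 0.8)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_clamped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sctdir.translation"):
            val = gan_loss(np.array([1.5]), np.array([0.5]))
        assert np.isfinite(val)
        assert any("clamping" in r.message for r in caplog.records)


class TestTotalLoss:
    def test_zero_weights_equal_gan(self, tiny_model, tiny_image):
        disc = PatchDiscriminator(base_channels=4, rng=np.random.default_rng(0))
        cfg = LossConfig(lambda_x=0.0, lambda_y=0.0, patches_per_layer=8)
        total, parts = total_loss(tiny_model, disc, tiny_image, tiny_image, cfg, seed=0)
        assert total == pytest.approx(parts["L_GAN"], rel=1e-9)

    def test_default_weights_are_one(self):
        cfg = LossConfig()
        assert cfg.lambda_x == 1.0 and cfg.lambda_y == 1.0

    def test_components_finite_at_random_init(self, tiny_model, tiny_image):
        disc = PatchDiscriminator(base_channels=4, rng=np.random.default_rng(1))
        total, parts = total_loss(tiny_model, disc, tiny_image, tiny_image, seed=0)
        assert np.isfinite(total)
        assert all(np.isfinite(v) for v in parts.values())
        assert total == pytest.approx(
            parts["L_GAN"] + parts["L_NCE_X"] + parts["L_NCE_Y"], rel=1e-6)


class TestLrSchedule:
    def test_full_scale_defaults(self):
        cfg = TrainConfig()  # full-scale defaults
        assert lr_schedule(1, cfg) == 2e-4
        assert lr_schedule(50, cfg) == 2e-4
        assert lr_schedule(200, cfg) == 0.0
        # linear in between
        assert lr_schedule(125, cfg) == pytest.approx(2e-4 * 75 / 150)
        assert lr_schedule(51, cfg) == pytest.approx(2e-4 * 149 / 150)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(total_epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)
        with pytest.raises(ValueError):
            TrainConfig(gan_mode="wasserstein")


class TestTrainTranslation:
    def test_micro_run_completes_with_finite_losses(self):
        rng = np.random.default_rng(0)
        xs = [ImageGrid(rng.uniform(-500, 100, (8, 8))) for _ in range(3)]
        ys = [ImageGrid(rng.uniform(-500, 100, (8, 8))) for _ in range(3)]
        spec = GeneratorSpec(base_channels=4, n_res_blocks=1, tap_layers=(0, 1),
                             hu_window=(-500, 100))
        model, log = train_translation(xs, ys, spec, LossConfig(patches_per_layer=4),
                               TrainConfig(total_epochs=2, warm_epochs=1, seed=0))
        assert len(log) == 2
        for entry in log:
            assert np.isfinite(entry["L_GAN"])
            assert np.isfinite(entry["L_NCE_X"])
            assert np.isfinite(entry["L_NCE_Y"])
        assert log[0]["LR"] == 2e-4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        xs = [ImageGrid(rng.uniform(-500, 100, (8, 8))) for _ in range(2)]
        ys = [ImageGrid(rng.uniform(-500, 100, (8, 8))) for _ in range(2)]
        spec = GeneratorSpec(base_channels=4, n_res_blocks=1, tap_layers=(0, 1),
                             hu_window=(-500, 100))
        kwargs = dict(generator_spec=spec, loss_config=LossConfig(patches_per_layer=4),
                      train_config=TrainConfig(total_epochs=1, warm_epochs=1, seed=7))
        m1, log1 = train_translation(xs, ys, **kwargs)
        m2, log2 = train_translation(xs, ys, **kwargs)
        assert log1 == log2
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_translation([], [ImageGrid(np.zeros((8, 8)))])


class TestTranslate:
    def test_geometry_conserved(self, tiny_model, tiny_image):
        out = translate(tiny_image, tiny_model)
        assert out.shape == tiny_image.shape
        assert out.spacing == tiny_image.spacing
        assert out.origin == tiny_image.origin
        assert np.all(np.isfinite(out.values))

    def test_deterministic(self, tiny_model, tiny_image):
        a = translate(tiny_image, tiny_model)
        b = translate(tiny_image, tiny_model)
        np.testing.assert_array_equal(a.values, b.values)

    def test_3d_slicewise_equals_stacked_2d(self, tiny_model, tiny_image):
        vol = stack_slices(tiny_image, 3)
        out3d = translate(vol, tiny_model)
        out2d = translate(tiny_image, tiny_model)
        for k in range(3):
            np.testing.assert_allclose(out3d.values[:, :, k], out2d.values, atol=1e-6)

    def test_checkpoint_roundtrip(self, tiny_model, tiny_image, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = TranslationModel.load(path)
        np.testing.assert_allclose(
            translate(tiny_image, loaded).values,
            translate(tiny_image, tiny_model).values, atol=1e-6)


def test_intensity_normalization_roundtrip(rng):
    window = (-1000.0, 200.0)
    vals = rng.uniform(-1000, 200, size=(16, 16))
    back = denormalize_intensities(normalize_intensities(vals, window), window)
    np.testing.assert_allclose(back, vals, atol=1e-9)
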