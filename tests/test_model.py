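"""Generator, twin discriminator, WFF, losses, training and tiled inference."""

import numpy as np
import pytest

from aorpe.model import (
    AblationVariant,
    CNNDiscriminatorSpec,
    Generator,
    GeneratorSpec,
    LossConfig,
    PGANRecovery,
    TrainConfig,
    TwinDiscriminator,
    TwinDiscriminatorSpec,
    build_nets,
    load_generator,
    pgan_step,
    recover,
    save_generator,
    train_pgan,
    twin_similarity,
    wff_fuse,
)
from aorpe.nn import Tensor

TOY_GEN = GeneratorSpec(depth=3, base_channels=8)
TOY_TWIN = TwinDiscriminatorSpec(depth=3, base_channels=8, tap_levels=(0, 1))
TOY_CNN = CNNDiscriminatorSpec(depth=3, base_channels=8)


def toy_nets(variant="PGAN", seed=0):
    return build_nets(variant, TOY_GEN, TOY_TWIN, TOY_CNN, TrainConfig(seed=seed))


def random_batch(rng, n=4, p=32):
    return (rng.random((n, p, p), dtype=np.float32) for _ in range(3))


class TestGenerator:
    def test_output_shape_and_range(self, rng):
        gen = Generator(TOY_GEN)
        for shape in [(1, 1, 32, 32), (2, 1, 75, 75)]:
            out = gen(Tensor(rng.random(shape, dtype=np.float32)))
            assert out.data.shape == shape
            assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(depth=0)


class TestWFF:
    def test_constant_map_closed_form(self):
        maps = [Tensor(np.ones((1, c, 4, 4))) for c in (8, 16, 32)]
        fused = wff_fuse(maps, (0.2, 0.2, 1.0))
        expected = np.concatenate([
            np.full(8, 0.2), np.full(16, 0.2), np.full(32, 1.0)])
        np.testing.assert_allclose(fused.data[0], expected)

    def test_degenerate_weights_match_last_layer_pooling(self, rng):
        """Weights (0,0,1) zero the intermediate slots, leaving exactly the
        pooled last-layer vector — the no-WFF ablation's information."""
        maps = [Tensor(rng.random((1, c, 4, 4))) for c in (8, 16, 32)]
        fused = wff_fuse(maps, (0.0, 0.0, 1.0))
        assert np.all(fused.data[0, :24] == 0.0)
        np.testing.assert_allclose(
            fused.data[0, 24:], maps[2].data.mean(axis=(2, 3))[0], rtol=1e-6)

    def test_homogeneity(self, rng):
        maps = [Tensor(rng.random((1, c, 4, 4))) for c in (4, 8, 16)]
        f1 = wff_fuse(maps, (0.2, 0.2, 1.0))
        f2 = wff_fuse(maps, (0.4, 0.4, 2.0))
        np.testing.assert_allclose(f2.data, 2.0 * f1.data, rtol=1e-6)

    def test_wrong_tap_count_rejected(self):
        with pytest.raises(ValueError):
            wff_fuse([Tensor(np.ones((1, 2, 2, 2)))] * 2, (1, 1, 1))


class TestTwinDiscriminator:
    def test_identical_inputs_give_bias_score(self, rng):
        """Zero feature distance makes the score squash(bias), independent of
        image content."""
        d1 = TwinDiscriminator(TOY_TWIN, rng=np.random.default_rng(3))
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        expected = 1.0 / (1.0 + np.exp(-float(d1.head.bias.data[0])))
        assert twin_similarity(d1, a, a) == pytest.approx(expected, abs=1e-6)
        assert twin_similarity(d1, b, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetry(self, rng):
        d1 = TwinDiscriminator(TOY_TWIN, rng=np.random.default_rng(4))
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert twin_similarity(d1, a, b) == pytest.approx(
            twin_similarity(d1, b, a), abs=1e-7)

    def test_shape_mismatch_rejected(self, rng):
        d1 = TwinDiscriminator(TOY_TWIN)
        with pytest.raises(ValueError):
            d1.similarity_logit(
                Tensor(rng.random((1, 1, 32, 32))), Tensor(rng.random((1, 1, 16, 16))))

    def test_weight_sharing_after_training(self, rng):
        """The two branches are one storage: parameters stay identical after
        optimisation steps because they are literally the same arrays."""
        nets = toy_nets("PGAN")
        batch = tuple(random_batch(rng))
        for _ in range(2):
            pgan_step(batch, nets, LossConfig())
        d1 = nets.d1
        a = Tensor(rng.random((1, 1, 32, 32), dtype=np.float32))
        fa1 = d1.branch_features(a).data
        fa2 = d1.branch_features(a).data  # second "branch" pass
        np.testing.assert_array_equal(fa1, fa2)
        assert len({id(p) for p in d1.parameters()}) == len(d1.parameters())


class TestPganStep:
    def test_content_only_reduces_to_regression(self, rng):
        """With only the content weight the generator loss equals the plain
        pixel norm computed directly on the batch."""
        nets = build_nets("PGAN", TOY_GEN, TOY_TWIN, TOY_CNN, TrainConfig(seed=1))
        spk, avg, alt = random_batch(rng)
        fake = nets.generator(Tensor(spk[:, None])).data[:, 0]
        expected_l1 = np.abs(fake - avg).mean()
        losses = pgan_step(
            (spk, avg, alt), nets,
            LossConfig(adv_d2_weight=0.0, adv_d1_weight=0.0, content_weight=1.0))
        assert losses["generator_total"] == pytest.approx(expected_l1, rel=1e-5)

    def test_g_d2_variant_is_conventional_gan(self, rng):
        nets = toy_nets("G_D2")
        assert nets.d1 is None and nets.d2 is not None
        losses = pgan_step(tuple(random_batch(rng)), nets,
                           LossConfig.for_variant("G_D2"))
        assert "d2_adv" in losses and "d1_sim_adv" not in losses

    def test_step_determinism(self, rng):
        spk, avg, alt = random_batch(rng)
        results = []
        for _ in range(2):
            nets = toy_nets("PGAN", seed=5)
            results.append(pgan_step((spk, avg, alt), nets, LossConfig()))
        assert results[0] == results[1]

    def test_all_variants_run_from_config_alone(self, rng):
        batch = tuple(random_batch(rng))
        for variant in AblationVariant:
            nets = toy_nets(variant.value)
            losses = pgan_step(batch, nets, LossConfig.for_variant(variant))
            assert np.isfinite(losses["generator_total"])

    def test_no_wff_variant_zeroes_intermediate_weights(self):
        nets = toy_nets("G_D2_D1_noWFF")
        assert nets.d1.spec.wff_weights == (0.0, 0.0, 1.0)


class TestTraining:
    def test_zero_epochs_returns_untrained_generator(self, rng):
        x, y, alt = random_batch(rng)
        gen, log = train_pgan((x, y, alt), train_cfg=TrainConfig(epochs=0),
                              gen_spec=TOY_GEN, twin_spec=TOY_TWIN, cnn_spec=TOY_CNN)
        assert log == []
        assert isinstance(gen, Generator)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_pgan((np.zeros((0, 8, 8)), np.zeros((0, 8, 8))))

    def test_loss_log_is_finite_and_complete(self, rng):
        x, y, alt = random_batch(rng, n=8, p=32)
        gen, log = train_pgan(
            (x, y, alt), train_cfg=TrainConfig(epochs=2, batch_size=4, seed=2),
            gen_spec=TOY_GEN, twin_spec=TOY_TWIN, cnn_spec=TOY_CNN)
        assert len(log) == 4
        for entry in log:
            for key in ("d2_adv", "d1_sim_adv", "content", "generator_total"):
                assert np.isfinite(entry[key])

    def test_checkpoint_round_trip(self, tmp_path, rng):
        x, y, alt = random_batch(rng)
        gen, _ = train_pgan((x, y, alt), train_cfg=TrainConfig(epochs=1, seed=3),
                            gen_spec=TOY_GEN, twin_spec=TOY_TWIN, cnn_spec=TOY_CNN)
        save_generator(gen, tmp_path / "gen.npz", manifest={"seed": 3})
        loaded = load_generator(tmp_path / "gen.npz")
        img = rng.random((48, 48))
        np.testing.assert_array_equal(
            recover(gen, img, patch_px=32), recover(loaded, img, patch_px=32))


class TestRecover:
    def test_patch_sized_input_matches_tiled_path(self, rng):
        gen = Generator(TOY_GEN)
        img = rng.random((32, 32))
        direct = recover(gen, img, patch_px=32)
        padded = recover(gen, np.pad(img, ((0, 16), (0, 16)), mode="reflect"),
                         patch_px=32)[:32, :32]
        assert np.abs(direct[:16, :16] - padded[:16, :16]).max() < 1e-3

    def test_blend_weights_cover_all_pixels(self, rng):
        """Tiling a 300x200 image with 150 px patches covers every pixel with
        normalised blend weights."""
        from aorpe.model import _cosine_window, _cover_offsets

        h, w, p = 300, 200, 150
        stride = p // 2
        win = _cosine_window(p)
        wacc = np.zeros((h, w))
        for oy in _cover_offsets(h, p, stride):
            for ox in _cover_offsets(w, p, stride):
                wacc[oy : oy + p, ox : ox + p] += win
        assert wacc.min() > 0.0
        # normalised blend: contributions sum to exactly 1 after division
        ones = wacc / wacc
        np.testing.assert_allclose(ones, 1.0, atol=1e-6)

    def test_inference_determinism(self, rng):
        gen = Generator(TOY_GEN)
        img = rng.random((80, 64))
        np.testing.assert_array_equal(
            recover(gen, img, patch_px=32), recover(gen, img, patch_px=32))

    def test_undersized_input_rejected(self, rng):
        gen = Generator(TOY_GEN)
        with pytest.raises(ValueError):
            recover(gen, rng.random((16, 16)), patch_px=32)


class TestEstimatorInterface:
    def test_params_round_trip(self):
        est = PGANRecovery(epochs=3)
        params = est.get_params()
        est2 = PGANRecovery(**params)
        assert est2.get_params() == params
        est2.set_params(epochs=5)
        assert est2.epochs == 5
        with pytest.raises(ValueError):
            est2.set_params(bogus=1)

    def test_fit_transform_shapes(self, rng):
        x = rng.random((8, 32, 32))
        y = rng.random((8, 32, 32))
        est = PGANRecovery(variant="G_D2", epochs=1, batch_size=4, depth=3,
                           base_channels=4, seed=0)
        out = est.fit(x, y).transform(x[:2])
        assert out.shape == (2, 32, 32)
        assert est.history_
        single = est.transform(x[0])
        assert single.shape == (32, 32)

    def test_unfitted_transform_rejected(self, rng):
        with pytest.raises(RuntimeError):
            PGANRecovery().transform(rng.random((32, 32)))
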