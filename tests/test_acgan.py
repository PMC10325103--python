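"""ac-GAN architecture arithmetic, loss values, training, persistence."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pgan import LabeledImageSet, one_hot
from pgan.acgan import (ACGAN, ACGANResults, DiscriminatorSpec,
                        GanTrainingConfig, GeneratorSpec, acgan_loss,
                        discriminator_output_shape, generator_output_shape)
from pgan.phantom import PhantomConfig, generate_phantom


class TestArchitectureArithmetic:
    def test_reference_generator_produces_nine_slice_64x64(self):
        assert generator_output_shape(GeneratorSpec()) == (9, 64, 64)

    def test_reference_generator_first_layer_output_is_4x4(self):
        one_layer = GeneratorSpec(
            deconv_layers=GeneratorSpec().deconv_layers[:1])
        assert generator_output_shape(one_layer) == (512, 4, 4)

    def test_reference_discriminator_trunk_collapses_to_64x1x1(self):
        assert discriminator_output_shape(
            DiscriminatorSpec(), (9, 64, 64)) == (64, 1, 1)

    @pytest.mark.parametrize("size", [8, 16, 32])
    def test_desk_specs_round_trip_at_reduced_sizes(self, size):
        gs = GeneratorSpec.desk(size, n_slices=9, base_channels=8)
        assert generator_output_shape(gs) == (9, size, size)
        ds = DiscriminatorSpec.desk(size, base_channels=8)
        assert discriminator_output_shape(ds, (9, size, size))[1:] == (1, 1)

    def test_non_power_of_two_size_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec.desk(24)
        with pytest.raises(ValueError):
            DiscriminatorSpec.desk(4)

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel exceeds"):
            discriminator_output_shape(DiscriminatorSpec(), (9, 8, 8))


class TestLoss:
    def test_hand_computed_value(self):
        # L_D = log 0.9 + log 0.8; L_C = (log 0.7 + log 0.6) / 2
        l, l_d, l_c = acgan_loss([0.9], [0.8], [[0.7, 0.2, 0.1],
                                                [0.3, 0.6, 0.1]], [1, 2])
        assert l_d == pytest.approx(np.log(0.9) + np.log(0.8))
        assert l_c == pytest.approx((np.log(0.7) + np.log(0.6)) / 2)
        assert l == pytest.approx(l_d + l_c)

    def test_coin_flip_discriminator_gives_three_log_half(self):
        l, l_d, l_c = acgan_loss([0.5], [0.5], [[0.5, 0.25, 0.25]], [1])
        assert l_d == pytest.approx(2 * np.log(0.5))
        assert l == pytest.approx(3 * np.log(0.5))

    def test_alpha_scales_only_the_class_term(self):
        args = ([0.9], [0.8], [[0.7, 0.2, 0.1]], [1])
        l0, l_d, l_c = acgan_loss(*args, alpha=0.0)
        l2, _, _ = acgan_loss(*args, alpha=2.0)
        assert l0 == pytest.approx(l_d)
        assert l2 == pytest.approx(l_d + 2 * l_c)

    def test_zero_probabilities_are_clamped_to_finite_loss(self):
        l, _, _ = acgan_loss([0.0], [1.0], [[1.0, 0.0, 0.0]], [2])
        assert np.isfinite(l)

    @pytest.mark.parametrize("labels", [[0], [4]])
    def test_out_of_range_labels_rejected(self, labels):
        with pytest.raises(ValueError):
            acgan_loss([0.5], [0.5], [[1 / 3] * 3], labels)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            acgan_loss([0.5], [0.5], [[1 / 3] * 3], [1], alpha=-1)


@pytest.fixture(scope="module")
def tiny_train():
    """Eight distinct 16x16 training stacks with strong patient effects."""
    cfg = PhantomConfig(n_patients=8, scans_per_patient=1, vus_per_scan=1,
                        n_slices=9, height=16, width=16, noise_sd=0.08,
                        patient_effect_sd=0.5, seed=5)
    data = generate_phantom(cfg)
    return LabeledImageSet(images=data.images, labels=data.labels,
                           patient_ids=data.patient_ids,
                           split=np.full(len(data), "train", dtype=object))


def tiny_specs():
    return (GeneratorSpec.desk(16, n_slices=9, base_channels=8),
            DiscriminatorSpec.desk(16, base_channels=8))


@pytest.fixture(scope="module")
def smoke_fit(tiny_train):
    gs, ds = tiny_specs()
    cfg = GanTrainingConfig(epochs=3, batch_size=8, seed=0)
    return ACGAN(tiny_train, gs, ds, cfg).fit()


class TestTraining:
    def test_history_covers_every_iteration_with_finite_losses(self, smoke_fit):
        h = smoke_fit.history
        assert list(h["iteration"]) == list(range(len(h)))
        assert h["epoch"].max() == 2
        assert np.isfinite(h[["d_adv", "d_class", "g_adv", "g_class",
                              "d_loss", "g_loss"]].to_numpy()).all()
        # L_D and L_C are mean log-probabilities, hence non-positive
        assert (h["d_adv"] <= 0).all() and (h["d_class"] <= 0).all()

    def test_training_is_deterministic_for_fixed_seed(self, tiny_train):
        gs, ds = tiny_specs()
        cfg = GanTrainingConfig(epochs=1, batch_size=8, seed=4)
        a = ACGAN(tiny_train, gs, ds, cfg).fit()
        b = ACGAN(tiny_train, gs, ds, cfg).fit()
        assert a.history.equals(b.history)
        assert np.array_equal(a.generate([one_hot(1)], seed=0),
                              b.generate([one_hot(1)], seed=0))

    def test_mismatched_data_shape_rejected(self, tiny_train):
        gs = GeneratorSpec.desk(32, n_slices=9, base_channels=8)
        ds = DiscriminatorSpec.desk(32, base_channels=8)
        with pytest.raises(ValueError, match="does not match"):
            ACGAN(tiny_train, gs, ds, GanTrainingConfig(epochs=1))

    @pytest.mark.parametrize("bad", [
        {"lr_g": 0.0}, {"alpha": -0.1}, {"epochs": 0}, {"batch_size": 0}])
    def test_invalid_training_config_rejected(self, bad):
        with pytest.raises(ValueError):
            GanTrainingConfig(**bad).validate()


class TestGeneration:
    def test_output_shape_range_and_determinism(self, smoke_fit):
        imgs = smoke_fit.generate([one_hot(1), one_hot(2), one_hot(3)], seed=7)
        assert imgs.shape == (3, 9, 16, 16)
        assert imgs.min() >= -1.0 and imgs.max() <= 1.0
        again = smoke_fit.generate([one_hot(k) for k in (1, 2, 3)], seed=7)
        assert np.array_equal(imgs, again)

    def test_different_seeds_give_different_samples(self, smoke_fit):
        a = smoke_fit.generate([one_hot(1)], seed=0)
        b = smoke_fit.generate([one_hot(1)], seed=1)
        assert not np.array_equal(a, b)

    def test_morph_endpoints_match_one_hot_generations(self, smoke_fit):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((1, smoke_fit.gen_spec.noise_dim))
        stack = smoke_fit.morph(1, 3, n_steps=4, z=z)
        assert stack.shape == (5, 9, 16, 16)
        assert np.allclose(stack[0], smoke_fit.generate([one_hot(1)], z=z)[0])
        assert np.allclose(stack[-1], smoke_fit.generate([one_hot(3)], z=z)[0])

    def test_wrong_condition_width_rejected(self, smoke_fit):
        with pytest.raises(ValueError):
            smoke_fit.generate(np.ones((2, 4)) / 4)

    def test_classify_returns_normalized_posteriors(self, smoke_fit):
        post = smoke_fit.classify(smoke_fit.generate([one_hot(2)] * 4, seed=0))
        assert post.shape == (4, 3)
        assert np.allclose(post.sum(axis=1), 1.0)


def test_adversarial_training_learns_the_training_distribution(tiny_train):
    """After training on eight images, generated samples land much closer
    to the training set than an untrained generator's outputs, and the
    auxiliary head recovers the requested class — the conditional
    generative model has learned both appearance and conditioning."""
    gs, ds = tiny_specs()
    X = tiny_train.images.reshape(len(tiny_train), -1)

    def mean_nearest(res, n=24, seed=3):
        rng = np.random.default_rng(seed)
        conds = [one_hot(int(k)) for k in
                 tiny_train.labels[rng.integers(0, len(tiny_train), n)]]
        imgs = res.generate(conds, seed=seed)
        return cdist(imgs.reshape(n, -1), X).min(axis=1).mean()

    untrained = ACGAN(tiny_train, gs, ds,
                      GanTrainingConfig(epochs=1, batch_size=8, seed=0,
                                        lr_g=1e-12, lr_d=1e-12)).fit()
    trained = ACGAN(tiny_train, gs, ds,
                    GanTrainingConfig(epochs=600, batch_size=8, seed=0,
                                      lr_g=2e-3, lr_d=2e-3)).fit()
    assert mean_nearest(trained) < 0.5 * mean_nearest(untrained)

    imgs = trained.generate([one_hot(int(k)) for k in tiny_train.labels], seed=3)
    post = trained.classify(imgs)
    assert (post.argmax(axis=1) + 1 == tiny_train.labels).mean() >= 0.8


class TestPersistence:
    def test_save_load_roundtrip_preserves_samples_and_history(self, smoke_fit,
                                                               tmp_path):
        path = tmp_path / "model.pgan"
        smoke_fit.save(path)
        back = ACGANResults.load(path)
        assert np.allclose(back.generate([one_hot(2)], seed=5),
                           smoke_fit.generate([one_hot(2)], seed=5))
        assert np.allclose(back.classify(np.zeros((1, 9, 16, 16))),
                           smoke_fit.classify(np.zeros((1, 9, 16, 16))))
        assert back.history.equals(smoke_fit.history)
        assert back.gen_spec == smoke_fit.gen_spec
        assert back.disc_spec == smoke_fit.disc_spec

    def test_summary_reports_key_hyperparameters(self, smoke_fit):
        s = smoke_fit.summary()
        assert "alpha: 1.0" in s and "noise dim: 100" in s

    def test_history_csv_export(self, smoke_fit, tmp_path):
        out = tmp_path / "history.csv"
        smoke_fit.export_history_csv(out)
        import pandas as pd
        assert len(pd.read_csv(out)) == len(smoke_fit.history)
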