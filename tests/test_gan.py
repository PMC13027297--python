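"""Adversarial losses (closed forms), photometric augmentation, GAN
training smoke behaviour and manifest-expansion bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from aphidgrade import synthetic as syn
from aphidgrade.gan import (AugmentSpec, GanConfig, augment_dataset,
                            balance_allocation, discriminator_loss,
                            generator_loss, standard_augment, train_gan)


class TestLossClosedForms:
    def test_perfect_discriminator_limit(self):
        eps = 1e-6
        loss = discriminator_loss([1 - eps], [eps])
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_half_half_is_two_ln_two(self):
        assert discriminator_loss([0.5], [0.5]) == \
            pytest.approx(2 * np.log(2), abs=1e-9)

    def test_discriminator_loss_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            dr = rng.uniform(1e-4, 1 - 1e-4, size=8)
            df = rng.uniform(1e-4, 1 - 1e-4, size=8)
            assert discriminator_loss(dr, df) >= 0.0

    def test_boundary_values_are_clamped_not_infinite(self):
        assert np.isfinite(discriminator_loss([0.0, 1.0], [0.0, 1.0]))

    def test_generator_score_form(self):
        assert generator_loss([0.5, 0.5]) == pytest.approx(-0.5)
        assert generator_loss([0.0]) == pytest.approx(0.0)
        assert generator_loss([0.2, 0.8]) == pytest.approx(-0.5, abs=1e-7)

    def test_generator_minimax_form(self):
        assert generator_loss([0.5], form="minimax") == \
            pytest.approx(np.log(0.5), abs=1e-6)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            generator_loss([0.5], form="wasserstein")


class TestStandardAugment:
    def _img(self, seed=0):
        return np.random.default_rng(seed).random((32, 32, 3)).astype(np.float32)

    def test_identity_spec_is_identity(self):
        spec = AugmentSpec(rotation=0, brightness=0, contrast=0,
                           saturation=0, grayscale_prob=0)
        img = self._img()
        assert np.array_equal(standard_augment(img, spec, 0), img)

    def test_constant_image_at_mean_normalises_to_zero(self):
        mean = (0.3, 0.5, 0.7)
        spec = AugmentSpec(rotation=0, brightness=0, contrast=0,
                           saturation=0, grayscale_prob=0,
                           mean=mean, std=(0.2, 0.2, 0.2))
        img = np.broadcast_to(np.array(mean, np.float32),
                              (16, 16, 3)).copy()
        out = standard_augment(img, spec, 0)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_seed_determinism(self):
        spec = AugmentSpec()
        img = self._img(1)
        a = standard_augment(img, spec, 7)
        b = standard_augment(img, spec, 7)
        assert np.array_equal(a, b)
        c = standard_augment(img, spec, 8)
        assert not np.array_equal(a, c)

    def test_output_shape_preserved(self):
        out = standard_augment(self._img(2), AugmentSpec(), 3)
        assert out.shape == (32, 32, 3)


@pytest.fixture(scope="module")
def grade3_images():
    return np.stack([
        syn.render_image(3, 64, syn.child_seed(77, i)).pixels
        for i in range(64)])


class TestTrainGan:
    def test_history_length_and_determinism(self, grade3_images):
        cfg = GanConfig(image_side=32, epochs=2, batch_size=16, seed=5)
        gen1, h1 = train_gan(grade3_images, cfg)
        gen2, h2 = train_gan(grade3_images, cfg)
        assert len(h1["d_loss"]) == len(h1["g_loss"]) == 2
        assert h1["d_loss"][0] == h2["d_loss"][0]  # bit-identical
        assert h1["g_loss"] == h2["g_loss"]
        s1 = gen1.sample(2, seed=0)
        s2 = gen2.sample(2, seed=0)
        assert np.array_equal(s1, s2)

    def test_sample_shape_and_range(self, grade3_images):
        cfg = GanConfig(image_side=32, epochs=1, batch_size=16, seed=1)
        gen, _ = train_gan(grade3_images, cfg)
        imgs = gen.sample(3, seed=2)
        assert imgs.shape == (3, 32, 32, 3)
        assert imgs.min() >= 0.0 and imgs.max() <= 1.0

    def test_discriminator_improves_for_majority_of_seeds(self, grade3_images):
        """Weak smoke property: D loss drops from epoch 1 to epoch 5 in at
        least 2 of 3 seeds."""
        wins = 0
        for seed in (0, 1, 2):
            cfg = GanConfig(image_side=32, epochs=5, batch_size=16, seed=seed)
            _, hist = train_gan(grade3_images, cfg)
            if hist["d_loss"][4] < hist["d_loss"][0]:
                wins += 1
        assert wins >= 2

    def test_too_few_images_rejected(self, grade3_images):
        cfg = GanConfig(image_side=32, epochs=1, batch_size=16)
        with pytest.raises(ValueError):
            train_gan(grade3_images[:8], cfg)

    def test_bad_image_side_rejected(self):
        with pytest.raises(ValueError):
            GanConfig(image_side=48)


class _StubGenerator:
    """Synthetic stand-in emitting flat grey images, for bookkeeping tests."""

    def sample(self, n, seed):
        return np.full((n, 8, 8, 3), 0.5, np.float32)


def _field_scale_manifest():
    """1760 records with the realistic imbalanced class mix."""
    counts = {0: 419, 1: 429, 2: 516, 3: 396}
    rows = [{"path": f"img_{g}_{i}.png", "label": g, "source": "real",
             "seed": 0}
            for g, n in counts.items() for i in range(n)]
    return syn.DatasetManifest(pd.DataFrame(rows))


class TestAugmentDataset:
    def test_1760_to_2000_adds_exactly_240_gan_records(self):
        manifest = _field_scale_manifest()
        gens = {g: _StubGenerator() for g in range(4)}
        out = augment_dataset(manifest, 2000, gens, seed=0)
        assert len(out) == 2000
        added = out.records[out.records["source"] == "gan"]
        assert len(added) == 240

    def test_target_equal_current_is_noop(self):
        manifest = _field_scale_manifest()
        out = augment_dataset(manifest, 1760, {}, seed=0)
        assert out.records.equals(manifest.records)

    def test_spread_never_grows(self):
        manifest = _field_scale_manifest()
        before = manifest.class_counts()
        spread_before = max(before.values()) - min(before.values())
        out = augment_dataset(manifest, 2000,
                              {g: _StubGenerator() for g in range(4)}, seed=0)
        after = out.class_counts()
        assert max(after.values()) - min(after.values()) <= spread_before

    def test_smallest_class_filled_first(self):
        counts = balance_allocation({0: 10, 1: 4, 2: 10, 3: 10}, 6)
        assert counts == {0: 0, 1: 6, 2: 0, 3: 0}

    def test_original_records_unaltered(self):
        manifest = _field_scale_manifest()
        out = augment_dataset(manifest, 1800,
                              {g: _StubGenerator() for g in range(4)}, seed=0)
        assert out.records.iloc[:1760].equals(manifest.records)

    def test_target_below_current_rejected(self):
        with pytest.raises(ValueError):
            augment_dataset(_field_scale_manifest(), 1000, {}, seed=0)

    def test_images_written_when_dir_given(self, tmp_path):
        manifest = _field_scale_manifest()
        out = augment_dataset(manifest, 1765,
                              {g: _StubGenerator() for g in range(4)},
                              seed=0, out_dir=tmp_path, emit_side=16)
        gan_rows = out.records[out.records["source"] == "gan"]
        for p in gan_rows["path"]:
            img = syn.load_image(tmp_path / p)
            assert img.shape == (16, 16, 3)
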