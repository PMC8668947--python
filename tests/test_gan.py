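"""GAN losses against closed forms, training/sampling contracts, augmentation
arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramangan.dataset import SpectralAxis, class_counts
from ramangan.gan import (
    GanConfig,
    augment_balanced,
    augment_stratified,
    discriminator_value,
    generator_value,
    minimax_value,
    sample_synthetic,
    train_gan,
)
from tests.conftest import constant_dataset

EPS = 1e-7

probs = st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20)


class TestLossValues:
    def test_uninformative_discriminator(self):
        assert discriminator_value([0.5], [0.5]) == pytest.approx(2 * math.log(0.5))

    def test_hand_arithmetic(self):
        assert discriminator_value([0.9], [0.1]) == pytest.approx(2 * math.log(0.9))

    def test_clamping_keeps_logs_finite(self):
        v = discriminator_value([1.0], [0.0])
        assert np.isfinite(v)
        assert v == pytest.approx(2 * math.log(1 - EPS))

    def test_generator_values(self):
        assert generator_value([0.5]) == pytest.approx(math.log(0.5))
        assert generator_value([0.0]) == pytest.approx(math.log(1 - EPS))
        assert generator_value([0.9]) < generator_value([0.1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discriminator_value([], [0.5])
        with pytest.raises(ValueError):
            generator_value([])

    def test_nash_point_value(self):
        """A discriminator outputting 1/2 everywhere sits at the classic
        minimax optimum with value -2 ln 2."""
        assert minimax_value([0.5] * 10, [0.5] * 10) == pytest.approx(-2 * math.log(2))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(probs, probs)
    def test_closed_form_oracle(self, real, fake):
        """Both objectives equal their direct clamped-log recomputation and
        respect the stated upper bounds."""
        clamp = lambda p: min(max(p, EPS), 1 - EPS)
        expected_d = np.mean([math.log(clamp(p)) for p in real]) + np.mean(
            [math.log(1 - clamp(p)) for p in fake]
        )
        expected_g = np.mean([math.log(1 - clamp(p)) for p in fake])
        assert discriminator_value(real, fake) == pytest.approx(expected_d, abs=1e-12)
        assert generator_value(fake) == pytest.approx(expected_g, abs=1e-12)
        assert discriminator_value(real, fake) <= 2 * math.log(1 - EPS) + 1e-12
        assert generator_value(fake) <= math.log(1 - EPS) + 1e-12


class TestTrainGan:
    def test_zero_epochs(self, single_class_dataset):
        model = train_gan(single_class_dataset, GanConfig(epochs=0, seed=0))
        assert model.history_["disc_value"] == []
        ds = sample_synthetic(model, 5, random_state=1)
        assert ds.n == 5 and ds.X.shape[1] == single_class_dataset.d

    def test_determinism(self, single_class_dataset):
        cfg = GanConfig(epochs=5, seed=12)
        m1 = train_gan(single_class_dataset, cfg)
        m2 = train_gan(single_class_dataset, cfg)
        assert m1.history_ == m2.history_
        s1 = m1.sample(4, random_state=3)
        s2 = m2.sample(4, random_state=3)
        assert np.array_equal(s1, s2)

    def test_mixed_classes_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            train_gan(toy_dataset, GanConfig(epochs=1))

    def test_too_few_samples_rejected(self, single_class_dataset):
        with pytest.raises(ValueError):
            train_gan(single_class_dataset.subset([0]), GanConfig(epochs=1))

    def test_history_length_equals_epochs(self, single_class_dataset):
        model = train_gan(single_class_dataset, GanConfig(epochs=7, seed=0))
        assert len(model.history_["disc_value"]) == 7
        assert len(model.history_["gen_value"]) == 7

    def test_constant_dataset_convergence(self):
        """On identical noiseless spectra the generator collapses onto the
        single training point: mean of 64 samples within 0.05 per-feature RMS
        of the target in scaled units after 300 epochs."""
        rng = np.random.default_rng(5)
        axis_d32 = SpectralAxis(600.0, 1700.0, 32)
        spectrum = rng.uniform(0.5, 2.0, 32)
        data = constant_dataset(spectrum, 512, axis_d32)
        model = train_gan(data, GanConfig(epochs=300, seed=0))
        scaled = model.generator_.forward(
            np.random.default_rng(99).standard_normal((64, model.config.latent_dim)),
            train=False,
        )
        # constant features scale to 0 by convention, so the target is 0
        rms = float(np.sqrt((scaled.mean(axis=0) ** 2).mean()))
        assert rms < 0.05
        # in original units the residual carries over through the unit
        # divisor used for zero-span features
        back = model.sample(64, random_state=99)
        assert np.abs(back.mean(axis=0) - spectrum).max() < 0.2


class TestSampling:
    def test_sample_contracts(self, single_class_dataset):
        model = train_gan(single_class_dataset, GanConfig(epochs=2, seed=0))
        ds = sample_synthetic(model, 5, random_state=8)
        assert ds.n == 5
        assert set(ds.labels) == {"BCC"}
        assert all(ds.synthetic)
        assert set(ds.treated) == {"unknown"}
        assert np.array_equal(ds.X, sample_synthetic(model, 5, random_state=8).X)
        assert sample_synthetic(model, 0, random_state=1).n == 0

    def test_samples_within_scaler_range(self, single_class_dataset):
        """Sigmoid output + inverse min-max keeps samples inside the training
        envelope."""
        model = train_gan(single_class_dataset, GanConfig(epochs=2, seed=0))
        X = model.sample(20, random_state=0)
        lo = single_class_dataset.X.min(axis=0) - 1e-9
        hi = single_class_dataset.X.max(axis=0) + 1e-9
        assert np.all(X >= lo) and np.all(X <= hi)


class TestAugmentationArithmetic:
    @pytest.fixture
    def models(self, toy_dataset):
        return {
            c: train_gan(toy_dataset.class_subset(c), GanConfig(epochs=1, seed=i))
            for i, c in enumerate(toy_dataset.class_set)
        }

    def test_balanced_counts(self, toy_dataset, models):
        out = augment_balanced(toy_dataset, models, 4, random_state=0)
        assert class_counts(out) == {"BCC": 7, "NORMAL": 7, "SCC": 7}
        assert out.n == toy_dataset.n + 3 * 4

    def test_balanced_identity_at_zero(self, toy_dataset, models):
        out = augment_balanced(toy_dataset, models, 0, random_state=0)
        assert out.n == toy_dataset.n
        assert np.array_equal(out.X, toy_dataset.X)

    def test_stratified_counts_and_priors(self, toy_dataset, models):
        out = augment_stratified(toy_dataset, models, 2, random_state=0)
        counts_in = class_counts(toy_dataset)
        counts_out = class_counts(out)
        for c in toy_dataset.class_set:
            assert counts_out[c] == 3 * counts_in[c]
        priors_in = np.array([counts_in[c] for c in toy_dataset.class_set]) / toy_dataset.n
        priors_out = np.array([counts_out[c] for c in toy_dataset.class_set]) / out.n
        assert np.abs(priors_in - priors_out).max() < 1e-15

    def test_stratified_identity_at_zero(self, toy_dataset, models):
        assert augment_stratified(toy_dataset, models, 0, random_state=0).n == toy_dataset.n

    def test_missing_model_rejected(self, toy_dataset, models):
        del models["SCC"]
        with pytest.raises(ValueError):
            augment_balanced(toy_dataset, models, 1)
        with pytest.raises(ValueError):
            augment_stratified(toy_dataset, models, 1)

    def test_synthetic_samples_flagged(self, toy_dataset, models):
        out = augment_balanced(toy_dataset, models, 2, random_state=0)
        assert out.synthetic.sum() == 6
        assert not out.synthetic[: toy_dataset.n].any()
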