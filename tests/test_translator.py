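"""Conditional GAN: losses against independent oracles, architecture, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iedgan.data import SegmentSet
from iedgan.errors import (ConfigurationError, InvalidInputError,
                           InvalidParameterError, ShapeError)
from iedgan.nn import Tensor, concat
from iedgan.translator import (ChannelScaler, TranslatorConfig, adversarial_value,
                               build_discriminator, build_generator,
                               count_parameters, generator_objective, l2_distance,
                               train_translator, translate)


def _bce_oracle(p: np.ndarray, target: float) -> float:
    """Independent elementwise binary cross-entropy (mean log loss)."""
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))


class TestAdversarialValue:
    def test_half_half_closed_form(self):
        assert adversarial_value([0.5], [0.5]) == pytest.approx(2 * np.log(0.5))

    def test_discriminator_optimum_approaches_zero(self):
        assert adversarial_value([1 - 1e-9], [1e-9]) == pytest.approx(0.0, abs=1e-5)

    def test_equals_negated_bce_oracle_on_random_batches(self, rng):
        for _ in range(100):
            d_real = rng.uniform(1e-6, 1 - 1e-6, size=rng.integers(1, 40))
            d_fake = rng.uniform(1e-6, 1 - 1e-6, size=rng.integers(1, 40))
            expected = -(_bce_oracle(d_real, 1.0) + _bce_oracle(d_fake, 0.0))
            assert adversarial_value(d_real, d_fake) == pytest.approx(expected,
                                                                      rel=1e-6)

    def test_empty_batch_rejected(self):
        with pytest.raises(InvalidInputError):
            adversarial_value([], [0.5])


class TestL2Distance:
    def test_identity_is_zero(self, rng):
        y = rng.standard_normal((3, 64, 12))
        assert l2_distance(y, y) == 0.0

    def test_ones_vs_zeros_is_sqrt_768(self):
        assert l2_distance(np.ones((1, 64, 12)),
                           np.zeros((1, 64, 12))) == pytest.approx(np.sqrt(768))

    def test_mean_of_per_segment_norms(self):
        a = np.zeros((2, 64, 12))
        b = np.zeros((2, 64, 12))
        b[0, 0, 0] = 3.0
        b[1, 0, :2] = [4.0, 3.0]          # norms 3 and 5
        assert l2_distance(a, b) == pytest.approx(4.0)

    def test_matches_norm_oracle_on_random_batches(self, rng):
        for _ in range(100):
            y = rng.standard_normal((5, 64, 12))
            z = rng.standard_normal((5, 64, 12))
            expected = np.mean([np.linalg.norm(y[i] - z[i]) for i in range(5)])
            assert l2_distance(y, z) == pytest.approx(expected, rel=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            l2_distance(np.zeros((2, 64, 12)), np.zeros((3, 64, 12)))


class TestGeneratorObjective:
    def test_reduces_to_adversarial_term_at_lambda_zero(self, rng):
        d = rng.uniform(0.1, 0.9, 8)
        y = rng.standard_normal((8, 64, 12))
        z = rng.standard_normal((8, 64, 12))
        expected = -np.mean(np.log(d))
        assert generator_objective(d, y, z, 0.0) == pytest.approx(expected)

    def test_perfect_reconstruction_leaves_adversarial_term(self, rng):
        d = rng.uniform(0.1, 0.9, 4)
        y = rng.standard_normal((4, 64, 12))
        got = generator_objective(d, y, y, 100.0, mode="minimax")
        assert got == pytest.approx(np.mean(np.log(1 - d)))

    def test_arithmetic_composition(self):
        # adversarial term -1 (minimax: mean log(1-d) = -1), L2 = 2, lambda = 100
        d = np.full(3, 1 - np.exp(-1.0))
        y = np.zeros((3, 64, 12))
        z = np.zeros((3, 64, 12))
        z[:, 0, 0] = 2.0
        assert generator_objective(d, y, z, 100.0, mode="minimax") == pytest.approx(199.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidParameterError):
            generator_objective([0.5], np.zeros((1, 64, 12)), np.zeros((1, 64, 12)),
                                -1.0)

    @given(lam1=st.floats(0, 50), lam2=st.floats(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_lambda_when_error_positive(self, lam1, lam2):
        d = np.array([0.5])
        y = np.zeros((1, 64, 12))
        z = np.ones((1, 64, 12))
        lo, hi = sorted([lam1, lam2])
        assert generator_objective(d, y, z, lo) <= generator_objective(d, y, z, hi)


class TestArchitecture:
    def test_generator_shape_contract(self, rng):
        gen = build_generator(TranslatorConfig(seed=0))
        x = rng.standard_normal((3, 12, 64)).astype(np.float32)
        assert gen(Tensor(x)).shape == (3, 12, 64)

    def test_contracting_time_lengths_and_widths(self):
        cfg = TranslatorConfig(seed=0)
        gen = build_generator(cfg)
        widths = [blk.conv.weight.shape[0] for blk in gen.enc]
        assert widths == [16, 32, 64]
        t = 64
        for _ in gen.enc:
            t //= 2
        assert t == 8                      # 64 -> 32 -> 16 -> 8

    def test_discriminator_outputs_probability(self, rng):
        disc = build_discriminator(TranslatorConfig(seed=0))
        disc.eval()
        xy = rng.standard_normal((5, 24, 64)).astype(np.float32)
        p = disc(Tensor(xy)).data
        assert p.shape == (5, 1)
        assert ((p > 0) & (p < 1)).all()

    def test_discriminator_eval_mode_deterministic(self, rng):
        disc = build_discriminator(TranslatorConfig(seed=0))
        disc.eval()
        xy = Tensor(rng.standard_normal((2, 24, 64)).astype(np.float32))
        np.testing.assert_array_equal(disc(xy).data, disc(xy).data)

    def test_discriminator_rejects_wrong_shape(self, rng):
        disc = build_discriminator(TranslatorConfig(seed=0))
        with pytest.raises(ShapeError):
            disc(Tensor(rng.standard_normal((2, 12, 64))))

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            build_generator(TranslatorConfig(n_levels=7, seed=0))

    def test_discriminator_update_does_not_decrease_adversarial_value(self, rng):
        """One small discriminator ascent step on a frozen batch improves Eq.-style value."""
        from iedgan.nn import Adam

        cfg = TranslatorConfig(seed=3, dropout_rate=0.0)
        disc = build_discriminator(cfg)
        x = Tensor(rng.standard_normal((8, 12, 64)).astype(np.float32))
        y = Tensor(rng.standard_normal((8, 12, 64)).astype(np.float32))
        f = Tensor(rng.standard_normal((8, 12, 64)).astype(np.float32))

        def value():
            d_r = disc(concat([x, y], axis=1)).clip(1e-7, 1 - 1e-7)
            d_f = disc(concat([x, f], axis=1)).clip(1e-7, 1 - 1e-7)
            return d_r.log().mean() + (1.0 - d_f).log().mean()

        before = value().item()
        opt = Adam(disc.parameters(), lr=1e-4)
        loss = -value()
        disc.zero_grad()
        loss.backward()
        opt.step()
        assert value().item() >= before


class TestParameterCounting:
    def test_lone_convolution_count(self):
        from iedgan.nn import Conv1d
        conv = Conv1d(12, 16, 5, np.random.default_rng(0))
        assert conv.n_parameters() == 5 * 12 * 16 + 16        # 976

    def test_lone_dense_count(self):
        from iedgan.nn import Dense
        dense = Dense(16, 12, np.random.default_rng(0))
        assert dense.n_parameters() == 16 * 12 + 12           # 204

    def test_reference_architecture_within_budget(self):
        cfg = TranslatorConfig(seed=0)
        total = count_parameters(build_generator(cfg)) + \
            count_parameters(build_discriminator(cfg))
        assert total <= 250_000


@pytest.fixture(scope="module")
def small_train(tiny_segments):
    return tiny_segments[list(range(0, len(tiny_segments), 2))]


class TestTraining:
    def test_training_is_deterministic(self, small_train):
        cfg = TranslatorConfig(n_epochs=2, seed=4)
        a = train_translator(small_train, cfg)
        b = train_translator(small_train, cfg)
        assert a.loss_history == b.loss_history
        np.testing.assert_array_equal(a.generator.state()[0], b.generator.state()[0])

    def test_l2_decreases_over_training(self, small_train):
        tt = train_translator(small_train, TranslatorConfig(n_epochs=8, seed=1))
        assert tt.loss_history[-1]["l2"] < tt.loss_history[0]["l2"]

    def test_missing_intracranial_ground_truth_rejected(self, tiny_segments):
        import dataclasses
        broken = SegmentSet([dataclasses.replace(s, y_intracranial=None)
                             for s in tiny_segments[:4].segments])
        with pytest.raises(InvalidInputError):
            train_translator(broken, TranslatorConfig(n_epochs=1, seed=0))

    def test_translate_contract(self, small_train):
        tt = train_translator(small_train, TranslatorConfig(n_epochs=1, seed=0))
        x = small_train.stack_x()[:5]
        out = translate(tt, x)
        assert out.shape == (5, 64, 12)
        np.testing.assert_array_equal(out, translate(tt, x))   # inference determinism
        zero = translate(tt, np.zeros((2, 64, 12)))
        assert np.isfinite(zero).all()
        with pytest.raises(ShapeError):
            translate(tt, np.zeros((2, 32, 12)))


class TestChannelScaler:
    def test_round_trip(self, rng):
        x = rng.standard_normal((10, 64, 12)) * 40 + 3
        sc = ChannelScaler().fit(x)
        z = sc.transform(x)
        np.testing.assert_allclose(z.mean(axis=(0, 1)), 0.0, atol=1e-9)
        np.testing.assert_allclose(sc.inverse(z), x, atol=1e-9)
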