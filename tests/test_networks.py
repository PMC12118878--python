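import numpy as np
import pytest
from skimage.metrics import structural_similarity

from padenoise.networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    LossTerms,
    adversarial_generator_loss,
    bce_with_logits,
    build_discriminator,
    build_generator,
    build_unet_baseline,
    discriminator_objective,
    discriminator_output_shape,
    generator_objective,
    gradient_footprint,
    huber_loss,
    mae_loss,
    receptive_field,
    ssim_loss,
    ssim_loss_and_grad,
)
from padenoise.nn.layers import BatchNorm2D, Conv2D, ConvTranspose2D, Dropout


RNG = np.random.default_rng(0)


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestGeneratorGeometry:
    def test_output_matches_input_shape(self):
        gen = build_generator(GeneratorSpec(n_levels=4, base_filters=8), (32, 32), RNG)
        x = RNG.standard_normal((1, 1, 32, 32)).astype(np.float32)
        assert gen.forward(x, training=False).shape == (1, 1, 32, 32)

    def test_full_scale_depth_gives_unit_bottleneck(self):
        spec = GeneratorSpec()
        assert spec.resolve_levels(256) == 8
        assert 256 // 2**8 == 1  # bottleneck collapses to 1x1
        assert GeneratorSpec().resolve_levels(64) == 5

    def test_indivisible_or_non_square_sides_rejected(self):
        with pytest.raises(ValueError):
            build_generator(GeneratorSpec(n_levels=5), (48, 48), RNG)
        with pytest.raises(ValueError):
            build_generator(GeneratorSpec(n_levels=3), (32, 64), RNG)
        with pytest.raises(ValueError):
            GeneratorSpec(n_levels=6).resolve_levels(32)

    def test_unet_baseline_shares_skeleton(self):
        net = build_unet_baseline(GeneratorSpec(n_levels=3, base_filters=4), (16, 16), RNG)
        x = RNG.standard_normal((1, 1, 16, 16)).astype(np.float32)
        assert net.forward(x, training=False).shape == x.shape

    def test_backward_matches_numeric_gradient(self):
        gen = build_generator(GeneratorSpec(n_levels=3, base_filters=3), (16, 16),
                              np.random.default_rng(5))
        x = RNG.standard_normal((1, 1, 16, 16)).astype(np.float32)
        w = RNG.standard_normal((1, 1, 16, 16))

        def loss():
            return float((gen.forward(x, training=False) * w).sum())

        gen.forward(x, training=False)
        gx = gen.backward(w.astype(np.float32))
        ng = numeric_grad(loss, x)
        assert np.abs(gx - ng).max() / np.abs(ng).max() < 5e-3


class TestDiscriminatorGeometry:
    def test_patch_map_is_30x30_for_256_input(self):
        spec = DiscriminatorSpec()
        assert discriminator_output_shape(spec, (256, 256)) == (30, 30)

    def test_receptive_field_arithmetic_is_70(self):
        assert receptive_field(DiscriminatorSpec()) == 70

    @pytest.mark.parametrize("strides,expected", [
        ((2,), 4),
        ((2, 2), 10),
        ((2, 2, 1, 1), 34),
        ((2, 2, 2, 1, 1), 70),
    ])
    def test_receptive_field_for_ablated_stacks(self, strides, expected):
        assert receptive_field(DiscriminatorSpec(strides=strides)) == expected

    def test_gradient_footprint_probe_agrees_with_arithmetic(self):
        for strides, side in [((2, 2), 32), ((2, 2, 1, 1), 64)]:
            spec = DiscriminatorSpec(base_filters=4, strides=strides)
            disc = build_discriminator(spec, (side, side), np.random.default_rng(2))
            assert gradient_footprint(disc, (side, side)) == receptive_field(spec)

    def test_forward_map_matches_arithmetic(self):
        spec = DiscriminatorSpec(base_filters=4, strides=(2, 2, 1, 1))
        disc = build_discriminator(spec, (64, 64), RNG)
        out = disc.forward(RNG.standard_normal((1, 2, 64, 64)).astype(np.float32), False)
        assert out.shape[2:] == discriminator_output_shape(spec, (64, 64))

    def test_input_below_receptive_field_rejected(self):
        with pytest.raises(ValueError):
            build_discriminator(DiscriminatorSpec(), (64, 64), RNG)

    def test_first_block_unnormalized_and_final_leaky(self):
        disc = build_discriminator(DiscriminatorSpec(base_filters=4, strides=(2, 2, 1)),
                                   (32, 32), RNG)
        convs = [l for l in disc.layers if isinstance(l, Conv2D)]
        bns = [l for l in disc.layers if isinstance(l, BatchNorm2D)]
        assert len(convs) == 3  # 2 body blocks + head
        assert len(bns) == 1  # none on the first block, none on the head
        from padenoise.nn.layers import LeakyReLU
        assert isinstance(disc.layers[-1], LeakyReLU)


class TestLosses:
    def test_huber_zero_at_equality(self):
        x = RNG.random((8, 8))
        assert huber_loss(x, x) == 0.0

    @pytest.mark.parametrize("residual,expected", [(0.5, 0.125), (2.0, 1.5)])
    def test_huber_piecewise_values(self, residual, expected):
        pred = np.full((16, 16), residual)
        target = np.zeros((16, 16))
        assert huber_loss(pred, target, delta=1.0) == pytest.approx(expected)

    def test_huber_quadratic_to_linear_transition_is_smooth(self):
        target = np.zeros((1, 1))
        eps = 1e-6
        below = (huber_loss(np.full((1, 1), 1.0), target) -
                 huber_loss(np.full((1, 1), 1.0 - eps), target)) / eps
        above = (huber_loss(np.full((1, 1), 1.0 + eps), target) -
                 huber_loss(np.full((1, 1), 1.0), target)) / eps
        assert below == pytest.approx(1.0, abs=1e-4)
        assert above == pytest.approx(1.0, abs=1e-4)
        # exactly at |r| = delta the quadratic and linear branches agree
        assert huber_loss(np.full((1, 1), 1.0), target) == pytest.approx(0.5)

    def test_huber_monotone_in_residual_magnitude(self):
        target = np.zeros((4, 4))
        rs = np.linspace(0, 3, 25)
        vals = [huber_loss(np.full((4, 4), r), target) for r in rs]
        assert np.all(np.diff(vals) >= 0)

    def test_mae_values(self):
        x = RNG.random((8, 8))
        assert mae_loss(x, x) == 0.0
        assert mae_loss(x + 0.3, x) == pytest.approx(0.3)

    def test_ssim_loss_zero_for_identical_and_bounded(self):
        x = RNG.random((32, 32))
        assert ssim_loss(x, x) == pytest.approx(0.0, abs=1e-12)
        y = RNG.random((32, 32))
        val = ssim_loss(x, y)
        assert 0.0 <= val <= 2.0

    def test_ssim_matches_reference_implementation(self):
        a = RNG.random((32, 32))
        b = np.clip(a + 0.15 * RNG.standard_normal((32, 32)), 0, 1)
        ref = structural_similarity(a, b, data_range=1.0, gaussian_weights=True,
                                    sigma=1.5, use_sample_covariance=False)
        assert ssim_loss(a, b) == pytest.approx(1.0 - ref, abs=1e-6)

    def test_ssim_gradient_matches_numeric(self):
        a = RNG.random((16, 16))
        b = RNG.random((16, 16))
        _, g = ssim_loss_and_grad(a, b)
        for idx in [(8, 8), (0, 3), (15, 15)]:
            eps = 1e-5
            ap, am = a.copy(), a.copy()
            ap[idx] += eps
            am[idx] -= eps
            num = (ssim_loss(ap, b) - ssim_loss(am, b)) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_ssim_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim_loss(np.zeros((8, 8)), np.zeros((8, 8)))


class TestObjectives:
    def test_generator_objective_weighting(self):
        assert generator_objective(LossTerms(l_adv=0, l_huber=1, l_ssim=0)) == 100.0
        assert generator_objective(LossTerms()) == 0.0
        assert generator_objective(
            LossTerms(l_adv=0.7, l_huber=0.02, l_ssim=0.05)) == pytest.approx(7.7)

    def test_generator_objective_linear_in_each_term(self):
        base = LossTerms(l_adv=0.3, l_huber=0.01, l_ssim=0.02)
        v0 = generator_objective(base)
        assert generator_objective(LossTerms(1.3, 0.01, 0.02)) - v0 == pytest.approx(1.0)
        assert generator_objective(LossTerms(0.3, 1.01, 0.02)) - v0 == pytest.approx(100.0)
        assert generator_objective(LossTerms(0.3, 0.01, 1.02)) - v0 == pytest.approx(100.0)

    def test_discriminator_chance_level_is_two_log_two(self):
        zeros = np.zeros((1, 1, 5, 5))  # logit 0 -> sigmoid 0.5
        assert discriminator_objective(zeros, zeros) == pytest.approx(2 * np.log(2))

    def test_perfect_discrimination_loss_near_zero(self):
        big = np.full((1, 1, 5, 5), 20.0)
        assert discriminator_objective(big, -big) < 1e-6

    def test_adversarial_term_is_bce_against_ones(self):
        logits = RNG.standard_normal((1, 1, 4, 4))
        assert adversarial_generator_loss(logits) == pytest.approx(
            bce_with_logits(logits, 1.0))


class TestDropout:
    def test_zeroes_half_the_units_in_training(self):
        d = Dropout(0.5, np.random.default_rng(0))
        x = np.ones((1, 4, 100, 100), dtype=np.float32)
        y = d.forward(x, training=True)
        assert (y == 0).mean() == pytest.approx(0.5, abs=0.01)
        # inverted scaling keeps the expectation
        assert y.mean() == pytest.approx(1.0, abs=0.02)

    def test_inactive_at_inference(self):
        d = Dropout(0.5, np.random.default_rng(0))
        x = np.ones((1, 1, 32, 32), dtype=np.float32)
        np.testing.assert_array_equal(d.forward(x, training=False), x)


def test_conv_transpose_is_adjoint_of_conv():
    """<Conv x, y> == <x, ConvT y> when sharing the same kernel geometry."""
    rng = np.random.default_rng(3)
    conv = Conv2D(2, 3, 4, 2, 1, rng)
    convT = ConvTranspose2D(3, 2, 4, 2, 1, rng)
    convT.w.value = conv.w.value.T.copy()  # share weights
    convT.b.value[...] = 0.0
    conv.b.value[...] = 0.0
    x = rng.standard_normal((1, 2, 8, 8)).astype(np.float32)
    y = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
    lhs = float((conv.forward(x, False) * y).sum())
    rhs = float((x * convT.forward(y, False)).sum())
    assert lhs == pytest.approx(rhs, rel=1e-5)
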