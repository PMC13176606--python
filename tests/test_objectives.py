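"""Loss formulas against brute-force oracles and hand-computed cases."""

import numpy as np
import pytest

from stimpute.data import ExpressionMatrix, SharedGeneMap, ValidationError, build_shared_map
from stimpute.networks import LATENT_SC, LATENT_ST, build_bundle
from stimpute.objectives import (
    LossBreakdown,
    LossWeights,
    cycle_loss,
    discriminator_hinge_loss,
    hinge_fake,
    hinge_real,
    identity_loss,
    identity_loss_from_decoded,
    pearson_rows,
    reconstruction_loss,
    total_translator_loss,
    translator_gan_loss,
)


def brute_mse(x, y):
    total, count = 0.0, 0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total += (x[i, j] - y[i, j]) ** 2
            count += 1
    return total / count


def brute_pearson(a, b):
    am, bm = sum(a) / len(a), sum(b) / len(b)
    cov = sum((x - am) * (y - bm) for x, y in zip(a, b))
    va = sum((x - am) ** 2 for x in a)
    vb = sum((y - bm) ** 2 for y in b)
    if va == 0 or vb == 0:
        return 0.0
    return cov / (va**0.5 * vb**0.5)


class TestReconstruction:
    def test_identical_inputs_zero(self, rng):
        x = rng.normal(size=(3, 4))
        assert reconstruction_loss(x, x) == 0.0

    def test_constant_offset(self):
        assert reconstruction_loss(np.zeros((1, 2)), np.ones((1, 2))) == 1.0

    def test_matches_two_loop_oracle(self, rng):
        x, y = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert reconstruction_loss(x, y) == pytest.approx(brute_mse(x, y), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            reconstruction_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestIdentityLoss:
    def _shared(self, n):
        return SharedGeneMap([f"s{i}" for i in range(n)], np.arange(n), np.arange(n))

    def test_perfect_agreement_is_zero(self, rng):
        x = rng.normal(size=(4, 3))
        loss = identity_loss_from_decoded(x, x, x, x, self._shared(3))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_is_four(self, rng):
        x = rng.normal(size=(4, 3))
        loss = identity_loss_from_decoded(-x, x, -x, x, self._shared(3))
        assert loss == pytest.approx(4.0, abs=1e-10)

    def test_matches_per_cell_pearson_oracle(self, rng):
        dec_a, x_a = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        dec_b, x_b = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        loss = identity_loss_from_decoded(dec_a, x_a, dec_b, x_b, self._shared(3))
        rho_a = np.mean([brute_pearson(dec_a[i], x_a[i]) for i in range(2)])
        rho_b = np.mean([brute_pearson(dec_b[i], x_b[i]) for i in range(2)])
        assert loss == pytest.approx((1 - rho_a) + (1 - rho_b), abs=1e-10)

    def test_zero_variance_cell_contributes_one(self, rng):
        x = rng.normal(size=(2, 3))
        dec = x.copy()
        dec[0] = 5.0  # constant output for cell 0: rho treated as 0
        loss = identity_loss_from_decoded(dec, x, x, x, self._shared(3))
        assert loss == pytest.approx(0.5, abs=1e-10)

    def test_empty_shared_set_errors(self, rng):
        x = rng.normal(size=(2, 3))
        empty = SharedGeneMap([], np.array([], int), np.array([], int))
        with pytest.raises(ValidationError, match="shared genes"):
            identity_loss_from_decoded(x, x, x, x, empty)

    def test_nonshared_columns_have_exactly_zero_effect(self, rng):
        # only columns 0 and 2 are shared; perturbing column 1 must not move the loss
        shared = SharedGeneMap(["a", "b"], np.array([0, 1]), np.array([0, 2]))
        x_st = rng.normal(size=(3, 2))
        x_sc = rng.normal(size=(3, 4))
        dec_sc_space = rng.normal(size=(3, 4))
        dec_st_space = rng.normal(size=(3, 2))
        before = identity_loss_from_decoded(dec_sc_space, x_st, dec_st_space, x_sc, shared)
        perturbed = dec_sc_space.copy()
        perturbed[:, 1] += 123.0
        perturbed[:, 3] -= 7.0
        after = identity_loss_from_decoded(perturbed, x_st, dec_st_space, x_sc, shared)
        assert after == before  # exact, not approximate


class TestAdversarial:
    def test_hinge_margins_satisfied_zero(self):
        assert hinge_real(np.array([1.0, 2.0, 5.0])) == 0.0
        assert hinge_fake(np.array([-1.0, -3.0])) == 0.0

    def test_all_zero_scores_give_four(self):
        # each domain contributes max(0,1-0) + max(0,1+0) = 2
        z = np.zeros(6)
        total = hinge_real(z) + hinge_fake(z) + hinge_real(z) + hinge_fake(z)
        assert total == pytest.approx(4.0, abs=1e-12)

    def test_gan_loss_negated_means_oracle(self, rng):
        scores_a, scores_b = rng.normal(size=8), rng.normal(size=8)
        expected = -sum(scores_a) / 8 - sum(scores_b) / 8
        assert (-scores_a.mean() - scores_b.mean()) == pytest.approx(expected, abs=1e-10)

    def test_constant_plus_one_discriminators_give_minus_two(self, rng):
        bundle = build_bundle(6, 8, seed=0)

        class ConstantScore:
            def __call__(self, x, training=False, rng=None):
                return np.ones((x.shape[0], 1))

        class ZeroTranslator:
            def __init__(self, out_dim):
                self.out = out_dim

            def __call__(self, x, training=False, rng=None):
                return np.zeros((x.shape[0], self.out))

        bundle.disc_st = ConstantScore()
        bundle.disc_sc = ConstantScore()
        bundle.trans_st2sc = ZeroTranslator(LATENT_SC)
        bundle.trans_sc2st = ZeroTranslator(LATENT_ST)
        from stimpute.networks import encode

        z_st = encode(bundle, np.abs(rng.normal(size=(5, 6))), "ST")
        z_sc = encode(bundle, np.abs(rng.normal(size=(5, 8))), "SC")
        assert translator_gan_loss(bundle, z_st, z_sc) == pytest.approx(-2.0, abs=1e-12)


class TestCycleLoss:
    def test_non_negative(self, rng, small_sim):
        data, _ = small_sim
        bundle = build_bundle(data.st.n_genes, data.sc.n_genes, seed=1)
        loss = cycle_loss(bundle, data.st.values[:16], data.sc.values[:16])
        assert loss >= 0.0 and np.isfinite(loss)

    def test_identity_translators_reduce_to_autoencoder(self, rng):
        """With surrogate translators that cancel exactly, the cycle loss equals
        the plain reconstruction error of both autoencoders."""
        bundle = build_bundle(6, 8, seed=2)

        class PadTranslator:  # 256 -> 512, zero-padding
            def __call__(self, x, training=False, rng=None):
                return np.hstack([x, np.zeros_like(x)])

        class TruncateTranslator:  # 512 -> 256
            def __call__(self, x, training=False, rng=None):
                return x[:, :LATENT_ST]

        class PaddedEncoder:  # SC encoder whose upper half is always zero
            def __init__(self, inner):
                self.inner = inner
                self.in_dim = inner.in_dim

            def __call__(self, x, training=False, rng=None):
                z = self.inner(x, training=training, rng=rng)
                z[:, LATENT_ST:] = 0.0
                return z

        bundle.trans_st2sc = PadTranslator()
        bundle.trans_sc2st = TruncateTranslator()
        bundle.enc_sc = PaddedEncoder(bundle.enc_sc)

        x_st = np.abs(rng.normal(size=(5, 6)))
        x_sc = np.abs(rng.normal(size=(5, 8)))
        from stimpute.networks import decode, encode

        recon_st = reconstruction_loss(
            decode(bundle, encode(bundle, x_st, "ST"), "ST", clamp=False), x_st
        )
        recon_sc = reconstruction_loss(
            decode(bundle, encode(bundle, x_sc, "SC"), "SC", clamp=False), x_sc
        )
        assert cycle_loss(bundle, x_st, x_sc) == pytest.approx(recon_st + recon_sc, rel=1e-6)


class TestTotalLoss:
    def test_weighted_sum_hand_case(self):
        parts = LossBreakdown(identity=2.0, cycle=3.0, gan_translator=10.0)
        assert total_translator_loss(parts, LossWeights()) == pytest.approx(6.0, abs=1e-12)

    def test_all_zero_parts(self):
        assert total_translator_loss(LossBreakdown(), LossWeights()) == 0.0

    @pytest.mark.parametrize("scale", [0.0, 0.5, 2.0])
    def test_single_weight_scales_linearly(self, scale, rng):
        parts = LossBreakdown(identity=1.3, cycle=0.7, gan_translator=-0.2)
        base = total_translator_loss(parts, LossWeights(lambda_gan=0.1))
        scaled = total_translator_loss(parts, LossWeights(lambda_gan=0.1 * scale))
        assert scaled - base == pytest.approx(0.1 * (scale - 1) * parts.gan_translator, abs=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            LossWeights(lambda_cyc=-1.0)


def test_pearson_rows_matches_oracle(rng):
    a, b = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
    rho = pearson_rows(a, b)
    for i in range(6):
        assert rho[i] == pytest.approx(brute_pearson(a[i], b[i]), abs=1e-12)
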