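import numpy as np
import pytest

from symseg_da.autodiff import Tensor
from symseg_da.losses import (
    LossReport,
    LossWeights,
    adv_loss_source,
    adv_loss_target,
    consistency_loss,
    cycle_loss,
    generator_adv_loss,
    identity_loss,
    seg_supervised_loss,
    soft_dice_loss,
    total_loss,
)

LN2 = np.log(2.0)


class TestSoftDice:
    def test_identical_binary_masks(self, rng):
        mask = (rng.random((16, 16)) > 0.5).astype(np.float32)
        assert float(soft_dice_loss(mask, mask, eps=1.0)) < 1e-3

    def test_total_mismatch_closed_form(self):
        # all-ones vs all-zeros on 16x16 with eps=1: 1 - 1/257
        pred = np.ones((16, 16), np.float32)
        ref = np.zeros((16, 16), np.float32)
        expected = 1.0 - 1.0 / 257.0
        assert float(soft_dice_loss(pred, ref, eps=1.0)) == pytest.approx(expected, abs=1e-6)

    def test_symmetry(self, rng):
        a = rng.random((8, 8)).astype(np.float32)
        b = rng.random((8, 8)).astype(np.float32)
        assert float(soft_dice_loss(a, b)) == pytest.approx(float(soft_dice_loss(b, a)), abs=1e-7)

    def test_batch_mean(self, rng):
        a = rng.random((3, 1, 8, 8)).astype(np.float32)
        b = rng.random((3, 1, 8, 8)).astype(np.float32)
        per = [float(soft_dice_loss(a[i, 0], b[i, 0])) for i in range(3)]
        assert float(soft_dice_loss(a, b)) == pytest.approx(np.mean(per), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_gradient_flows(self, rng):
        pred = Tensor(rng.random((8, 8)).astype(np.float32), requires_grad=True)
        loss = soft_dice_loss(pred, (rng.random((8, 8)) > 0.5).astype(np.float32))
        loss.backward()
        assert pred.grad is not None and np.abs(pred.grad).max() > 0


class TestAdversarialLosses:
    def test_chance_scores_closed_form(self):
        half = np.full((4, 1, 8, 8), 0.5, np.float32)
        value = float(adv_loss_source(half, half, half, half))
        assert value == pytest.approx(4 * LN2, abs=1e-6)

    def test_perfect_discriminator_limit(self):
        real = np.full((4,), 1.0 - 1e-9, np.float32)
        fake = np.full((4,), 1e-9, np.float32)
        assert float(adv_loss_source(real, fake, real, fake)) < 1e-4

    def test_monotonicity_in_each_argument(self):
        base = np.full((4,), 0.5, np.float32)
        lo, hi = np.full((4,), 0.3, np.float32), np.full((4,), 0.7, np.float32)
        ref = float(adv_loss_source(base, base, base, base))
        # decreasing in real scores
        assert float(adv_loss_source(hi, base, base, base)) < ref
        assert float(adv_loss_source(base, base, hi, base)) < ref
        # increasing in fake scores
        assert float(adv_loss_source(base, hi, base, base)) > ref
        assert float(adv_loss_source(base, base, base, hi)) > ref
        assert float(adv_loss_source(lo, base, base, base)) > ref

    def test_target_loss_same_form(self):
        half = np.full((2,), 0.5, np.float32)
        assert float(adv_loss_target(half, half, half, half)) == pytest.approx(4 * LN2, abs=1e-6)

    def test_out_of_range_scores_rejected(self):
        bad = np.array([1.5], np.float32)
        ok = np.array([0.5], np.float32)
        with pytest.raises(ValueError):
            adv_loss_source(bad, ok, ok, ok)

    def test_generator_chance_closed_form(self):
        half = np.full((3, 1, 4, 4), 0.5, np.float32)
        assert float(generator_adv_loss(half, half)) == pytest.approx(2 * LN2, abs=1e-6)

    def test_generator_wins_limit(self):
        near_one = np.full((4,), 1.0 - 1e-9, np.float32)
        assert float(generator_adv_loss(near_one, near_one)) < 1e-4

    def test_generator_decreasing_in_scores(self):
        lo = np.full((4,), 0.4, np.float32)
        hi = np.full((4,), 0.6, np.float32)
        assert float(generator_adv_loss(hi, hi)) < float(generator_adv_loss(lo, lo))


class TestCycleIdentity:
    def test_identity_translators_zero(self, rng):
        xs = rng.random((2, 1, 8, 8)).astype(np.float32)
        xt = rng.random((2, 1, 8, 8)).astype(np.float32)
        assert float(cycle_loss(xs, xt, xs, xt)) == 0.0
        assert float(identity_loss(xs, xt, xs, xt)) == 0.0

    def test_constant_offset(self, rng):
        xs = rng.random((8, 8)).astype(np.float32) * 0.5
        xt = rng.random((8, 8)).astype(np.float32)
        assert float(cycle_loss(xs, xt, xs + 0.1, xt)) == pytest.approx(0.1, abs=1e-6)

    def test_identity_inversion_arithmetic(self):
        # G_{T->S}(x_s) = 1 - x_s on a constant 0.25 image, other term exact:
        # the printed two-term sum gives |1 - 2*0.25| = 0.5
        xs = np.full((8, 8), 0.25, np.float32)
        xt = np.full((8, 8), 0.7, np.float32)
        value = float(identity_loss(xs, xt, 1.0 - xs, xt))
        assert value == pytest.approx(0.5, abs=1e-6)

    def test_nonnegative(self, rng):
        for _ in range(5):
            xs, xt = rng.random((4, 4)), rng.random((4, 4))
            rs, rt = rng.random((4, 4)), rng.random((4, 4))
            assert float(cycle_loss(xs, xt, rs, rt)) >= 0.0

    def test_permutation_invariance(self, rng):
        xs = rng.random((16,)).astype(np.float32)
        rs = rng.random((16,)).astype(np.float32)
        xt = rng.random((16,)).astype(np.float32)
        perm = rng.permutation(16)
        v1 = float(cycle_loss(xs, xt, rs, xt))
        v2 = float(cycle_loss(xs[perm], xt, rs[perm], xt))
        assert v1 == pytest.approx(v2, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cycle_loss(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 5)), np.zeros((4, 4)))


class TestSegmentationLosses:
    def test_perfect_predictions(self, rng):
        gt = (rng.random((16, 16)) > 0.5).astype(np.float32)
        assert float(seg_supervised_loss(gt, gt, gt)) < 2e-3

    def test_additivity(self, rng):
        p1 = rng.random((16, 16)).astype(np.float32)
        p2 = rng.random((16, 16)).astype(np.float32)
        gt = (rng.random((16, 16)) > 0.5).astype(np.float32)
        total = float(seg_supervised_loss(p1, p2, gt))
        parts = float(soft_dice_loss(p1, gt)) + float(soft_dice_loss(p2, gt))
        assert total == pytest.approx(parts, abs=1e-6)

    def test_one_perfect_one_complement(self):
        gt = np.ones((16, 16), np.float32)
        wrong = np.zeros((16, 16), np.float32)
        expected = float(soft_dice_loss(wrong, gt))
        assert float(seg_supervised_loss(gt, wrong, gt)) == pytest.approx(expected, abs=1e-3)

    def test_missing_mask_rejected(self, rng):
        p = rng.random((8, 8))
        with pytest.raises(ValueError):
            seg_supervised_loss(p, p, None)

    def test_consistency_identical_maps(self, rng):
        # identical (near-binary) probability maps; for continuous maps the
        # smoothed Dice form is nonzero even at equality
        p = (rng.random((16, 16)) > 0.5).astype(np.float32)
        assert float(consistency_loss(p, p)) < 1e-3

    def test_consistency_complement_closed_form(self):
        ones = np.ones((16, 16), np.float32)
        zeros = np.zeros((16, 16), np.float32)
        assert float(consistency_loss(ones, zeros)) == pytest.approx(1 - 1 / 257, abs=1e-6)

    def test_consistency_symmetric(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert float(consistency_loss(a, b)) == pytest.approx(float(consistency_loss(b, a)), abs=1e-7)


class TestTotalLoss:
    def test_paper_weights_arithmetic(self):
        report, total = total_loss(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, LossWeights())
        assert float(total) == pytest.approx(16.0)
        assert report.total == pytest.approx(16.0)

    def test_zero_weights(self):
        weights = LossWeights(0.0, 0.0, 0.0, 0.0, 0.0)
        _, total = total_loss(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, weights)
        assert float(total) == 0.0

    def test_linearity_in_weights(self, rng):
        terms = rng.random(6)
        w1 = LossWeights(0.5, 0.7, 0.3, 2.0, 1.1)
        w2 = LossWeights(1.0, 1.4, 0.6, 4.0, 2.2)
        _, t1 = total_loss(*terms, w1)
        _, t2 = total_loss(*terms, w2)
        assert float(t2) == pytest.approx(2 * float(t1), rel=1e-6)

    def test_report_decomposition(self, rng):
        terms = rng.random(6)
        w = LossWeights(1.3, 0.4, 0.9, 7.0, 2.5)
        report, _ = total_loss(*terms, w)
        recomputed = (w.lambda_adv * (report.adv_s + report.adv_t)
                      + w.lambda_cycle * report.cycle + w.lambda_iden * report.iden
                      + w.lambda_seg * report.seg + w.lambda_consis * report.consis)
        assert report.total == pytest.approx(recomputed, abs=1e-6)

    def test_nan_term_named(self):
        with pytest.raises(ValueError, match="cycle"):
            total_loss(1.0, 1.0, np.nan, 1.0, 1.0, 1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_seg=-1.0)

    def test_gradients_reach_terms(self, rng):
        terms = [Tensor(np.array(v, np.float32), requires_grad=True) for v in rng.random(6)]
        _, total = total_loss(*terms)
        total.backward()
        assert all(t.grad is not None for t in terms)
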