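"""Loss terms: closed-form values, stage totals, adaptive weights, warm-up."""

import math

import numpy as np
import pytest

from plmt._autodiff import Tensor
from plmt.backbone import ConfigurationError, InputError
from plmt.losses import (LossWeights, adaptive_weights, consistency_loss,
                         cross_entropy, mse_loss, pseudo_loss, stage_a_total,
                         stage_c_total, supervised_loss, warmup_weight)


def _uniform_probs(batch, c, h, w):
    return np.full((batch, c, h, w), 1.0 / c, dtype=np.float32)


def _one_hot_probs(target, c):
    b, h, w = target.shape
    probs = np.zeros((b, c, h, w), dtype=np.float32)
    for cls in range(c):
        probs[:, cls][target == cls] = 1.0
    return probs


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self, rng):
        target = rng.integers(0, 2, size=(2, 4, 4))
        probs = _one_hot_probs(target, 2)
        assert cross_entropy(probs, target).item() == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("c,expected", [(2, math.log(2)), (3, math.log(3))])
    def test_uniform_prediction_closed_form(self, rng, c, expected):
        target = rng.integers(0, c, size=(2, 4, 4))
        loss = cross_entropy(_uniform_probs(2, c, 4, 4), target)
        assert loss.item() == pytest.approx(expected, rel=1e-5)

    def test_hand_computed_mean_over_pixels(self):
        # p[target] = 0.5 and 0.25 at two pixels -> (ln2 + ln4)/2
        probs = np.array([[[[0.5, 0.25]], [[0.5, 0.75]]]], dtype=np.float32)
        target = np.zeros((1, 1, 2), dtype=np.int64)
        loss = cross_entropy(probs, target)
        assert loss.item() == pytest.approx((math.log(2) + math.log(4)) / 2,
                                            rel=1e-5)

    def test_out_of_range_class_rejected(self):
        probs = _uniform_probs(1, 2, 4, 4)
        with pytest.raises(InputError):
            cross_entropy(probs, np.full((1, 4, 4), 2))

    def test_one_hot_target_stays_finite(self, rng):
        # zero probability on the target class must not produce inf
        target = np.zeros((1, 2, 2), dtype=np.int64)
        probs = _one_hot_probs(np.ones((1, 2, 2), dtype=np.int64), 2)
        assert np.isfinite(cross_entropy(probs, target).item())


class TestMseAndConsistency:
    def test_identical_inputs_zero(self, rng):
        a = rng.random((2, 2, 4, 4)).astype(np.float32)
        assert mse_loss(a, a).item() == 0.0

    def test_antipodal_single_pixel(self):
        a = np.array([1.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1)
        b = np.array([0.0, 1.0], dtype=np.float32).reshape(1, 2, 1, 1)
        assert mse_loss(a, b).item() == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.random((2, 3, 4, 4)).astype(np.float32)
        b = rng.random((2, 3, 4, 4)).astype(np.float32)
        assert mse_loss(a, b).item() == pytest.approx(mse_loss(b, a).item())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            mse_loss(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 4, 2)))

    def test_consistency_detaches_teacher(self):
        s = Tensor(np.full((1, 2, 2, 2), 0.5, dtype=np.float32), requires_grad=True)
        t = Tensor(np.full((1, 2, 2, 2), 0.25, dtype=np.float32), requires_grad=True)
        consistency_loss(s, t).backward()
        assert s.grad is not None
        assert t.grad is None

    def test_pseudo_loss_matches_cross_entropy(self, rng):
        pseudo = rng.integers(0, 3, size=(2, 4, 4))
        probs = rng.dirichlet(np.ones(3), size=(2, 4, 4)).transpose(0, 3, 1, 2)
        probs = probs.astype(np.float32)
        assert pseudo_loss(probs, pseudo).item() == pytest.approx(
            cross_entropy(probs, pseudo).item())


class TestAdaptiveWeights:
    def test_zero_gives_even_split(self):
        alpha, beta = adaptive_weights(0.0)
        assert (alpha, beta) == (0.5, 0.5)

    def test_log_three_gives_three_quarters(self):
        alpha, beta = adaptive_weights(math.log(3))
        assert alpha == pytest.approx(0.75)
        assert beta == pytest.approx(0.25)

    @pytest.mark.parametrize("z", [-30.0, -2.5, 0.0, 1.7, 30.0])
    def test_convexity_exact_for_any_finite_z(self, z):
        alpha, beta = adaptive_weights(z)
        assert alpha + beta == 1.0
        assert 0.0 < alpha < 1.0

    def test_nonfinite_z_rejected(self):
        with pytest.raises(InputError):
            adaptive_weights(float("nan"))

    def test_differentiable_in_z(self):
        z = Tensor(0.3, requires_grad=True)
        alpha, _ = adaptive_weights(z)
        alpha.backward()
        s = 1 / (1 + math.exp(-0.3))
        assert z.grad == pytest.approx(s * (1 - s), rel=1e-5)

    def test_convexity_survives_simulated_optimizer_steps(self, rng):
        z = 0.0
        for _ in range(1000):
            z += rng.normal(0.0, 0.05)
            alpha, beta = adaptive_weights(z)
            assert alpha + beta == 1.0


class TestWarmup:
    def test_endpoints(self):
        assert warmup_weight(1000, 1000) == pytest.approx(1.0)
        assert warmup_weight(0, 1000) == pytest.approx(math.exp(-5), rel=1e-9)
        assert warmup_weight(0, 1000) == pytest.approx(0.006738, abs=1e-6)

    def test_midpoint_closed_form(self):
        assert warmup_weight(500, 1000) == pytest.approx(math.exp(-1.25), rel=1e-9)
        assert warmup_weight(500, 1000) == pytest.approx(0.2865, abs=1e-4)

    def test_monotone_and_saturating(self):
        grid = [warmup_weight(t, 200) for t in range(0, 301, 10)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        assert warmup_weight(250, 200) == 1.0

    def test_invalid_tmax_rejected(self):
        with pytest.raises(ConfigurationError):
            warmup_weight(0, 0)


class TestStageTotals:
    def test_stage_a_worked_example(self):
        b = stage_a_total(1.0, 0.5, LossWeights(lambda_a=0.1), ramp=1.0)
        assert b.total_value == pytest.approx(1.05)
        assert b.pse is None

    def test_stage_a_degenerations(self):
        w = LossWeights(lambda_a=0.1)
        assert stage_a_total(0.7, 0.0, w, 1.0).total_value == pytest.approx(0.7)
        assert stage_a_total(0.7, 0.9, w, 0.0).total_value == pytest.approx(0.7)

    def test_stage_c_worked_example(self):
        w = LossWeights(lambda_c=0.1, K=1000.0, z=0.0)
        b = stage_c_total(1.0, 0.001, 0.8, w, ramp=1.0)
        assert b.total_value == pytest.approx(1.09)
        assert b.alpha == pytest.approx(0.5)
        assert b.beta == pytest.approx(0.5)

    def test_stage_c_temperature_zero_kills_consistency(self, rng):
        # with K=0 the total is bitwise independent of the consistency input
        w = LossWeights(lambda_c=0.1, K=0.0, z=0.37)
        totals = {stage_c_total(1.0, con, 0.8, w, 1.0).total_value
                  for con in rng.random(10)}
        assert len(totals) == 1
        _, beta = adaptive_weights(0.37)
        assert totals.pop() == pytest.approx(1.0 + 0.1 * beta * 0.8)

    def test_stage_c_total_matches_definition(self, rng):
        for _ in range(10):
            sup, con, pse = rng.random(3)
            lam, K, z, ramp = rng.random(4) * [1.0, 2000.0, 4.0, 1.0]
            w = LossWeights(lambda_c=lam, K=K, z=z - 2.0)
            alpha, beta = adaptive_weights(z - 2.0)
            expect = sup + lam * ramp * (alpha * K * con + beta * pse)
            assert stage_c_total(sup, con, pse, w, ramp).total_value == \
                pytest.approx(expect, rel=1e-5, abs=1e-6)

    def test_supervised_loss_rejects_empty_batch(self):
        with pytest.raises(InputError):
            supervised_loss(np.zeros((0, 2, 4, 4), dtype=np.float32),
                            np.zeros((0, 4, 4), dtype=np.int64))
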