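"""Loss oracles: brute-force NT-Xent, direct-summation masked loss,
closed-form presence loss, weighted-total identity, momentum update."""

import math

import numpy as np
import pytest

from modrepair.autodiff import Tensor
from modrepair.nn import Linear
from modrepair.objectives import (LossWeights, contrastive_loss, masked_loss,
                                  momentum_update, ntxent_pairwise,
                                  presence_loss, total_loss)


def ntxent_brute_force(a, b, tau):
    """Independent double-loop NT-Xent implementation."""
    z = np.concatenate([a, b])
    z = z / (np.linalg.norm(z, axis=1, keepdims=True) + 1e-12)
    n, n2 = len(a), len(z)
    total = 0.0
    for i in range(n2):
        pos = i + n if i < n else i - n
        denom = sum(math.exp(float(z[i] @ z[j]) / tau)
                    for j in range(n2) if j != i)
        total += -math.log(math.exp(float(z[i] @ z[pos]) / tau) / denom)
    return total / n2


class TestNTXent:
    def test_matches_brute_force_over_many_random_trials(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            p = int(rng.integers(2, 9))
            tau = float(rng.uniform(0.1, 2.0))
            a = rng.standard_normal((n, p))
            b = rng.standard_normal((n, p))
            assert abs(ntxent_pairwise(a, b, tau).item()
                       - ntxent_brute_force(a, b, tau)) < 1e-6

    def test_single_pair_degenerates_to_zero(self):
        a = np.random.default_rng(0).standard_normal((1, 4))
        assert ntxent_pairwise(a, a, 0.5).item() == 0.0

    def test_two_orthogonal_instances_closed_form(self):
        a = np.eye(2)
        expected = -math.log(math.exp(2.0) / (math.exp(2.0) + 2.0))
        assert abs(ntxent_pairwise(a, a, 0.5).item() - expected) < 1e-9

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((5, 8)), rng.standard_normal((5, 8))
        v1 = ntxent_pairwise(a, b, 0.5).item()
        v2 = ntxent_pairwise(a * 37.0, b * 37.0, 0.5).item()
        assert abs(v1 - v2) < 1e-9

    def test_zero_norm_row_is_guarded(self):
        a = np.zeros((2, 4))
        assert np.isfinite(ntxent_pairwise(a, a, 0.5).item())


class TestMaskedLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = {"a": np.ones((2, 3, 1))}
        assert masked_loss(x, {"a": x["a"].copy()}, {"a"}).item() == 0.0

    def test_empty_drop_set_returns_zero(self):
        x = {"a": np.ones((2, 3, 1))}
        assert masked_loss(x, x, set()).item() == 0.0

    def test_hand_computed_single_deviation(self):
        x = {"a": np.array([[[1.0], [2.0]], [[3.0], [4.0]]]).reshape(1, 2, 2)}
        xh = {"a": np.array([[[1.0], [2.0]], [[3.0], [5.0]]]).reshape(1, 2, 2)}
        assert abs(masked_loss(x, xh, {"a"}).item() - 0.25) < 1e-12

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(4)
        x = {m: rng.standard_normal((6, 5, 2)) for m in "abc"}
        xh = {m: rng.standard_normal((6, 5, 2)) for m in "abc"}
        drops = {m: rng.random(6) < 0.5 for m in "abc"}
        got = masked_loss(x, xh, drops).item()
        # direct per-window summation
        total, count = 0.0, 0
        for n in range(6):
            dropped = [m for m in "abc" if drops[m][n]]
            if not dropped:
                continue
            count += 1
            total += np.mean([np.mean((x[m][n] - xh[m][n]) ** 2)
                              for m in dropped])
        assert abs(got - total / count) < 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            masked_loss({"a": np.ones((1, 2, 2))},
                        {"a": np.ones((1, 2, 3))}, {"a"})


class TestContrastiveLoss:
    def test_single_modality_returns_zero(self):
        p = {"a": np.random.default_rng(0).standard_normal((4, 8))}
        assert contrastive_loss(p, np.ones((4, 1), bool), ["a"]).item() == 0.0

    def test_equals_mean_of_pairwise_calls(self):
        rng = np.random.default_rng(5)
        p = {m: rng.standard_normal((6, 8)) for m in "abc"}
        pres = np.ones((6, 3), bool)
        got = contrastive_loss(p, pres, list("abc"), tau=0.5).item()
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        want = np.mean([ntxent_pairwise(p[i], p[j], 0.5).item()
                        for i, j in pairs])
        assert abs(got - want) < 1e-10

    def test_aligned_projections_beat_shuffled(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((32, 8)) * 3
        pres = np.ones((32, 2), bool)
        aligned = contrastive_loss(
            {"a": base, "b": base + 0.01 * rng.standard_normal((32, 8))},
            pres, ["a", "b"]).item()
        shuffled = contrastive_loss(
            {"a": base, "b": base[rng.permutation(32)]},
            pres, ["a", "b"]).item()
        assert aligned < shuffled

    def test_pairs_respect_shared_presence(self):
        rng = np.random.default_rng(7)
        p = {m: rng.standard_normal((6, 4)) for m in "ab"}
        pres = np.zeros((6, 2), bool)
        pres[:, 0] = True
        pres[:3, 1] = True  # only first 3 windows shared
        got = contrastive_loss(p, pres, ["a", "b"], tau=0.5).item()
        want = ntxent_pairwise(p["a"][:3], p["b"][:3], 0.5).item()
        assert abs(got - want) < 1e-12


class TestPresenceLoss:
    def test_perfect_probabilities_near_zero(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert presence_loss(y, y).item() < 1e-5

    def test_uniform_probability_is_log_two(self):
        y = np.array([[1.0, 0.0]])
        p = np.full((1, 2), 0.5)
        assert abs(presence_loss(p, y).item() - math.log(2)) < 1e-12

    def test_scalar_closed_form(self):
        assert abs(presence_loss(np.array([[0.9]]), np.array([[1.0]])).item()
                   - (-math.log(0.9))) < 1e-12


class TestTotalLoss:
    def test_published_weighting(self):
        lt, bd = total_loss(0.2, 0.4, 0.0, LossWeights())
        assert abs(bd.l_total - 0.4) < 1e-12

    def test_all_zero(self):
        lt, _ = total_loss(0.0, 0.0, 0.0, LossWeights())
        assert lt.item() == 0.0

    def test_superposition_linearity(self):
        w = LossWeights(lambda_rec=0.7, lambda_con=0.3, lambda_pres=0.2)
        l1, _ = total_loss(1.0, 0.0, 0.0, w)
        l2, _ = total_loss(0.0, 1.0, 0.0, w)
        l3, _ = total_loss(0.0, 0.0, 1.0, w)
        combined, _ = total_loss(2.0, 3.0, 4.0, w)
        assert abs(combined.item() - (2 * l1.item() + 3 * l2.item()
                                      + 4 * l3.item())) < 1e-12

    def test_ablation_weight_zeroing(self):
        masked_only, _ = total_loss(0.5, 9.9, 0.0,
                                    LossWeights(lambda_con=0.0))
        assert abs(masked_only.item() - 0.5) < 1e-12
        con_only, _ = total_loss(9.9, 0.5, 0.0,
                                 LossWeights(lambda_rec=0.0))
        assert abs(con_only.item() - 0.25) < 1e-12

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_rec=-0.1)


class TestMomentumUpdate:
    def test_extremes_and_arithmetic(self):
        online = [Tensor(np.array([1.0]), requires_grad=True)]
        target = [Tensor(np.array([0.0]), requires_grad=True)]
        momentum_update(online, target, m=1.0)
        assert target[0].data[0] == 0.0
        momentum_update(online, target, m=0.996)
        assert abs(target[0].data[0] - 0.004) < 1e-12
        momentum_update(online, target, m=0.0)
        assert target[0].data[0] == 1.0

    def test_module_structure_update(self):
        rng = np.random.default_rng(0)
        a = Linear(3, 2, rng)
        b = Linear(3, 2, np.random.default_rng(1))
        before = b.weight.data.copy()
        momentum_update(a, b, m=0.5)
        np.testing.assert_allclose(
            b.weight.data, 0.5 * before + 0.5 * a.weight.data, atol=1e-7)

    def test_structure_mismatch_raises(self):
        with pytest.raises(ValueError):
            momentum_update([Tensor(np.zeros(2))], [Tensor(np.zeros(3))])
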