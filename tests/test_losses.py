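"""SSIM, structural losses, balanced cross-entropy and the total objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from densicount import (
    DensityMap,
    LossConfig,
    SegmentationMap,
    masked_structural_loss,
    ssim_index,
    structural_loss,
    total_loss,
    weighted_cross_entropy,
)
from densicount.losses import (
    masked_structural_loss_grad,
    weighted_cross_entropy_grad,
)
from densicount.targets import ContractError


def ssim_oracle(x, y, c1=0.01, c2=0.03):
    """Closed-form whole-map SSIM, written independently of the implementation."""
    mx, my = np.mean(x), np.mean(y)
    vx, vy = np.var(x), np.var(y)
    cov = np.mean((x - mx) * (y - my))
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


def pool_oracle(x, k):
    if k == 1:
        return x
    h, w = x.shape
    x = x[: h - h % k, : w - w % k]
    return x.reshape(h // k, k, w // k, k).mean(axis=(1, 3))


class TestSSIM:
    def test_identical_maps_give_one(self, rng):
        x = rng.random((8, 8))
        assert ssim_index(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_identical_constant_maps_give_one(self):
        x = np.full((5, 5), 3.7)
        assert ssim_index(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_random_pairs_match_formula_oracle(self, rng):
        for _ in range(100):
            x, y = rng.random((4, 4)), rng.random((4, 4))
            assert ssim_index(x, y) == pytest.approx(ssim_oracle(x, y), abs=1e-12)

    def test_never_exceeds_one(self, rng):
        for _ in range(200):
            x, y = rng.random((6, 6)), rng.random((6, 6)) * 5
            assert ssim_index(x, y) <= 1.0 + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            ssim_index(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_windowed_variant_also_one_for_identical(self, rng):
        x = rng.random((12, 12))
        cfg = LossConfig(window=5)
        assert ssim_index(x, x, cfg) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10))
    def test_symmetry_property(self, seed, scale):
        r = np.random.default_rng(seed)
        x, y = r.random((5, 7)), r.random((5, 7)) * scale
        assert ssim_index(x, y) == pytest.approx(ssim_index(y, x), rel=1e-12)


class TestStructuralLoss:
    def test_identical_maps_give_zero(self, rng):
        x = rng.random((16, 16))
        assert structural_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_single_level_equals_one_minus_ssim(self, rng):
        x, y = rng.random((8, 8)), rng.random((8, 8))
        cfg = LossConfig(n_levels=1)
        assert structural_loss(x, y, cfg) == pytest.approx(
            1 - ssim_index(x, y, cfg), abs=1e-12
        )

    def test_three_levels_match_pool_then_ssim_oracle(self, rng):
        for _ in range(50):
            x, y = rng.random((16, 16)), rng.random((16, 16))
            expect = np.mean(
                [1 - ssim_oracle(pool_oracle(x, k), pool_oracle(y, k)) for k in (1, 2, 4)]
            )
            assert structural_loss(x, y) == pytest.approx(expect, abs=1e-12)

    def test_nonnegative_for_random_maps(self, rng):
        for _ in range(1000):
            x, y = rng.random((6, 6)), rng.random((6, 6)) * rng.uniform(0.1, 4)
            assert structural_loss(x, y, LossConfig(n_levels=2)) >= 0.0

    def test_small_map_reduces_levels_with_warning(self, rng):
        x, y = rng.random((2, 2)), rng.random((2, 2))
        with pytest.warns(UserWarning):
            value = structural_loss(x, y, LossConfig(n_levels=4))
        assert value >= 0.0


class TestMaskedStructuralLoss:
    def test_all_ones_mask_reduces_to_structural_loss(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        mask = np.ones((16, 16))
        assert masked_structural_loss(x, y, mask) == structural_loss(x, y)

    def test_all_zeros_mask_gives_zero(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert masked_structural_loss(x, y, np.zeros((16, 16))) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_identical_maps_any_mask_give_zero(self, rng):
        x = rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.5).astype(float)
        assert masked_structural_loss(x, x, mask) == pytest.approx(0.0, abs=1e-12)

    def test_random_mask_matches_mask_pool_ssim_oracle(self, rng):
        for _ in range(50):
            x, y = rng.random((16, 16)), rng.random((16, 16))
            m = (rng.random((16, 16)) > 0.4).astype(float)
            expect = np.mean(
                [
                    1 - ssim_oracle(pool_oracle(x * m, k), pool_oracle(y * m, k))
                    for k in (1, 2, 4)
                ]
            )
            assert masked_structural_loss(x, y, m) == pytest.approx(expect, abs=1e-12)

    def test_non_binary_mask_rejected(self, rng):
        x = rng.random((8, 8))
        with pytest.raises(ContractError):
            masked_structural_loss(x, x, np.full((8, 8), 0.5))
        with pytest.raises(ContractError):
            masked_structural_loss(
                x, x, SegmentationMap(np.full((8, 8), 0.5), mode="probability")
            )

    def test_gradient_matches_finite_differences(self, rng):
        cfg = LossConfig()
        x, y = rng.random((8, 8)), rng.random((8, 8))
        m = (rng.random((8, 8)) > 0.4).astype(float)
        _, g = masked_structural_loss_grad(x, y, m, cfg)
        eps = 1e-6
        for i, j in [(0, 0), (3, 5), (7, 7), (2, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            num = (
                masked_structural_loss_grad(xp, y, m, cfg)[0]
                - masked_structural_loss_grad(xm, y, m, cfg)[0]
            ) / (2 * eps)
            assert g[i, j] == pytest.approx(num, abs=1e-7)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_is_tiny(self, rng):
        y = (rng.random((10, 10)) > 0.5).astype(float)
        assert weighted_cross_entropy(y, y) <= 1e-5

    def test_single_positive_cell_at_half(self):
        v = weighted_cross_entropy(np.array([[0.5]]), np.array([[1.0]]))
        assert v == pytest.approx(-np.log(0.5), abs=1e-9)  # 0.693147...

    def test_single_negative_cell_at_half_is_downweighted(self):
        v = weighted_cross_entropy(np.array([[0.5]]), np.array([[0.0]]))
        assert v == pytest.approx(0.5 * -np.log(0.5), abs=1e-9)  # 0.346574...

    def test_h_one_recovers_standard_bce(self, rng):
        p = rng.uniform(0.01, 0.99, (12, 12))
        y = (rng.random((12, 12)) > 0.5).astype(float)
        ours = weighted_cross_entropy(p, y, LossConfig(h=1.0))
        oracle = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_random_instances_match_formula_oracle(self, rng):
        cfg = LossConfig()
        for _ in range(100):
            p = rng.uniform(0.01, 0.99, (5, 5))
            y = (rng.random((5, 5)) > 0.5).astype(float)
            oracle = -np.mean(y * np.log(p) + cfg.h * (1 - y) * np.log(1 - p))
            assert weighted_cross_entropy(p, y, cfg) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_along_path_toward_target(self, rng):
        y = (rng.random((8, 8)) > 0.5).astype(float)
        p0 = rng.uniform(0.05, 0.95, (8, 8))
        values = [
            weighted_cross_entropy(p0 + t * (np.clip(y, 0.01, 0.99) - p0), y)
            for t in np.linspace(0, 0.95, 12)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        cfg = LossConfig()
        p = rng.uniform(0.05, 0.95, (6, 6))
        y = (rng.random((6, 6)) > 0.5).astype(float)
        _, g = weighted_cross_entropy_grad(p, y, cfg)
        eps = 1e-7
        for i, j in [(0, 0), (2, 4), (5, 5)]:
            pp, pm = p.copy(), p.copy()
            pp[i, j] += eps
            pm[i, j] -= eps
            num = (
                weighted_cross_entropy_grad(pp, y, cfg)[0]
                - weighted_cross_entropy_grad(pm, y, cfg)[0]
            ) / (2 * eps)
            assert g[i, j] == pytest.approx(num, abs=1e-6)


class TestTotalLoss:
    def test_zero_components(self):
        assert total_loss(0.0, 0.0) == 0.0

    def test_default_weighting(self):
        assert total_loss(0.2, 1.0) == pytest.approx(0.3, abs=1e-12)

    def test_random_components_match_arithmetic(self, rng):
        for _ in range(20):
            sl, ce, lam = rng.random(3)
            cfg = LossConfig(lambda_seg=lam)
            assert total_loss(sl, ce, cfg) == pytest.approx(sl + lam * ce, abs=1e-12)

    def test_container_types_accepted(self, rng):
        d = DensityMap(rng.random((8, 8)))
        s = SegmentationMap((rng.random((8, 8)) > 0.5).astype(float), mode="binary")
        assert masked_structural_loss(d, d, s) == pytest.approx(0.0, abs=1e-12)
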