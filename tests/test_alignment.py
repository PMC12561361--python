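"""Alignment machinery versus exhaustive-enumeration and finite-difference
oracles, plus the soft-limit and restricted-search bounds."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neuroscribe import alignment as al
from oracles import (
    dtw_brute,
    gibbs_path_average,
    soft_tdi_brute,
    softdtw_brute,
)


def random_pair(rng, max_len=5, dims=2):
    m = int(rng.integers(1, max_len + 1))
    n = int(rng.integers(1, max_len + 1))
    return rng.normal(size=(m, dims)), rng.normal(size=(n, dims))


class TestPairwiseCost:
    def test_identical_single_points(self):
        assert al.pairwise_cost([(0, 0)], [(0, 0)]) == pytest.approx(
            np.array([[0.0]])
        )

    def test_forced_squared_distances(self):
        D = al.pairwise_cost([(0, 0), (1, 0)], [(0, 1)])
        assert D == pytest.approx(np.array([[1.0], [2.0]]))

    def test_transpose_symmetry(self, rng):
        y, z = rng.normal(size=(4, 3)), rng.normal(size=(3, 3))
        ref = np.array(
            [[np.sum((yi - zj) ** 2) for zj in z] for yi in y]
        )
        assert al.pairwise_cost(y, z) == pytest.approx(ref)
        assert al.pairwise_cost(z, y) == pytest.approx(ref.T)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimensionality"):
            al.pairwise_cost(np.zeros((3, 2)), np.zeros((3, 3)))


class TestHardDtw:
    def test_identical_sequences_zero_diagonal(self, rng):
        y = rng.normal(size=(6, 2))
        dist, path = al.dtw(y, y)
        assert dist == pytest.approx(0.0, abs=1e-12)
        assert path == [(i, i) for i in range(6)]

    def test_single_cell(self):
        dist, path = al.dtw([0.0], [3.0])
        assert dist == pytest.approx(9.0)
        assert path == [(0, 0)]

    def test_matches_enumeration_on_short_pairs(self, rng):
        for _ in range(25):
            y, z = random_pair(rng, dims=1)
            D = al.pairwise_cost(y, z)
            dist, path = al.dtw(y, z)
            assert dist == pytest.approx(dtw_brute(D), rel=1e-8)
            assert sum(D[i, j] for i, j in path) == pytest.approx(dist)

    def test_path_is_admissible(self, rng):
        y, z = rng.normal(size=(7, 2)), rng.normal(size=(5, 2))
        _, path = al.dtw(y, z)
        assert path[0] == (0, 0) and path[-1] == (6, 4)
        steps = {(b[0] - a[0], b[1] - a[1]) for a, b in zip(path, path[1:])}
        assert steps <= {(1, 0), (0, 1), (1, 1)}

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            al.dtw([], [1.0])

    def test_normalized_dtw_is_distance_per_path_cell(self, rng):
        assert al.normalized_dtw([0.0], [3.0]) == pytest.approx(9.0)
        y, z = rng.normal(size=(5, 1)), rng.normal(size=(5, 1))
        D = al.pairwise_cost(y, z)
        dist, path = al.dtw(y, z)
        assert dist == pytest.approx(dtw_brute(D), rel=1e-8)
        assert al.normalized_dtw(y, z) == pytest.approx(dist / len(path))
        assert al.normalized_dtw(y, y) == pytest.approx(0.0, abs=1e-12)


class TestFastDtw:
    def test_identical_is_zero(self, rng):
        y = rng.normal(size=(40, 2))
        dist, _ = al.fast_dtw(y, y, radius=1)
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_smooth_pair_equals_exact(self):
        t = np.linspace(0, 2 * np.pi, 32)
        y = np.column_stack([np.sin(t), np.cos(t)])
        z = np.column_stack([np.sin(t + 0.3), np.cos(t + 0.3)])
        exact, _ = al.dtw(y, z)
        approx, _ = al.fast_dtw(y, z, radius=2)
        assert approx == pytest.approx(exact, rel=1e-10)

    def test_lower_bounded_by_exact_on_spiky_pairs(self, rng):
        for _ in range(10):
            y = rng.normal(size=(33, 1)) * rng.choice([1, 10], size=(33, 1))
            z = rng.normal(size=(29, 1)) * rng.choice([1, 10], size=(29, 1))
            exact, _ = al.dtw(y, z)
            for radius in (1, 2):
                approx, path = al.fast_dtw(y, z, radius=radius)
                assert approx >= exact - 1e-9
                assert path[0] == (0, 0) and path[-1] == (32, 28)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            al.fast_dtw([1.0], [1.0], radius=0)


class TestSoftMin:
    def test_equal_entries_closed_form(self):
        assert al.soft_min([2.0] * 5, 0.3) == pytest.approx(2.0 - 0.3 * np.log(5))

    def test_two_values_formula(self):
        assert al.soft_min([0.0, 1.0], 1.0) == pytest.approx(-np.log(1 + np.exp(-1)))

    def test_stable_for_tiny_gamma(self):
        val = al.soft_min([0.0, 1000.0], 0.001)
        assert np.isfinite(val)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_bounded_by_min(self, rng):
        vals = rng.normal(size=8)
        assert al.soft_min(vals, 0.5) <= vals.min()

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            al.soft_min([1.0], 0.0)


class TestSoftDtw:
    def test_matches_enumeration(self, rng):
        for _ in range(20):
            y, z = random_pair(rng, max_len=4)
            gamma = float(rng.uniform(0.05, 1.0))
            ref = softdtw_brute(al.pairwise_cost(y, z), gamma)
            assert al.soft_dtw(y, z, gamma) == pytest.approx(ref, rel=1e-8)

    def test_bounded_by_hard_dtw(self, rng):
        for _ in range(10):
            y, z = random_pair(rng, max_len=6)
            assert al.soft_dtw(y, z, 0.1) <= al.dtw(y, z)[0] + 1e-12

    def test_gamma_to_zero_limit(self, rng):
        y, z = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        hard, _ = al.dtw(y, z)
        assert abs(al.soft_dtw(y, z, 1e-4) - hard) <= 1e-2


class TestRelaxedPath:
    def test_matches_gibbs_average(self, rng):
        for _ in range(15):
            y, z = random_pair(rng, max_len=4)
            gamma = float(rng.uniform(0.05, 1.0))
            ref = gibbs_path_average(al.pairwise_cost(y, z), gamma)
            A = al.relaxed_path(y, z, gamma).weights
            assert A == pytest.approx(ref, abs=1e-8)

    def test_weights_in_unit_interval_corners_one(self, rng):
        y, z = rng.normal(size=(7, 2)), rng.normal(size=(5, 2))
        A = al.relaxed_path(y, z, 0.3).weights
        assert np.all(A >= -1e-12) and np.all(A <= 1 + 1e-12)
        assert A[0, 0] == pytest.approx(1.0) and A[-1, -1] == pytest.approx(1.0)

    def test_equals_finite_difference_gradient(self, rng):
        y, z = rng.normal(size=(4, 1)), rng.normal(size=(3, 1))
        gamma = 0.4
        D = al.pairwise_cost(y, z)
        A = al.relaxed_path(y, z, gamma).weights
        from neuroscribe import _dp

        eps = 1e-6
        for i in range(D.shape[0]):
            for j in range(D.shape[1]):
                Dp = D.copy(); Dp[i, j] += eps
                Dm = D.copy(); Dm[i, j] -= eps
                fd = (
                    _dp.softdtw_forward(Dp, gamma)[-1, -1]
                    - _dp.softdtw_forward(Dm, gamma)[-1, -1]
                ) / (2 * eps)
                assert A[i, j] == pytest.approx(fd, abs=1e-4)


class TestSoftTdi:
    def test_single_cell_is_zero(self):
        assert al.soft_tdi([1.0], [5.0]) == pytest.approx(0.0)

    def test_matches_enumeration(self, rng):
        for _ in range(15):
            y, z = random_pair(rng, max_len=4)
            gamma = float(rng.uniform(0.05, 1.0))
            for normalized in (True, False):
                params = al.DilateParams(0.5, gamma, normalized)
                omega = al.omega_matrix(len(y), len(z), normalized)
                ref = soft_tdi_brute(al.pairwise_cost(y, z), gamma, omega)
                assert al.soft_tdi(y, z, params) == pytest.approx(
                    ref, rel=1e-8, abs=1e-10
                )

    def test_nonnegative(self, rng):
        y, z = rng.normal(size=(6, 2)), rng.normal(size=(4, 2))
        assert al.soft_tdi(y, z, al.DilateParams(0.5, 0.2)) >= 0


class TestDilate:
    def test_alpha_endpoints(self, rng):
        y, z = rng.normal(size=(5, 2)), rng.normal(size=(4, 2))
        p1 = al.DilateParams(alpha=1.0, gamma=0.1)
        p0 = al.DilateParams(alpha=0.0, gamma=0.1)
        assert al.dilate_loss(y, z, p1) == pytest.approx(al.soft_dtw(y, z, 0.1))
        assert al.dilate_loss(y, z, p0) == pytest.approx(al.soft_tdi(y, z, p0))

    def test_small_gamma_combination_vs_enumeration(self, rng):
        y, z = rng.normal(size=(3, 1)), rng.normal(size=(3, 1))
        params = al.DilateParams(alpha=0.5, gamma=0.001)
        D = al.pairwise_cost(y, z)
        ref = 0.5 * softdtw_brute(D, 0.001) + 0.5 * soft_tdi_brute(
            D, 0.001, al.omega_matrix(3, 3, True)
        )
        assert al.dilate_loss(y, z, params) == pytest.approx(ref, rel=1e-8)

    @given(
        alpha=st.floats(0.1, 0.9),
        gamma=st.floats(1e-4, 1.0),
    )
    def test_continuous_in_hyperparameters(self, alpha, gamma):
        rng = np.random.default_rng(7)
        y, z = rng.normal(size=(10, 2)), rng.normal(size=(12, 2))
        val = al.dilate_loss(y, z, al.DilateParams(alpha, gamma))
        assert np.isfinite(val)

    def test_gradient_matches_finite_differences(self, rng):
        y, z = rng.normal(size=(5, 2)), rng.normal(size=(4, 2))
        params = al.DilateParams(alpha=0.5, gamma=0.2)
        _, grad = al.dilate_value_and_grad(y, z, params)
        eps = 1e-6
        for a in range(z.shape[0]):
            for b in range(2):
                zp = z.copy(); zp[a, b] += eps
                zm = z.copy(); zm[a, b] -= eps
                fd = (
                    al.dilate_loss(y, zp, params) - al.dilate_loss(y, zm, params)
                ) / (2 * eps)
                assert grad[a, b] == pytest.approx(fd, abs=5e-4)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            al.DilateParams(alpha=1.5)
        with pytest.raises(ValueError):
            al.DilateParams(gamma=-1.0)


class TestWarpAndOffsets:
    def test_identity_warp(self, rng):
        y = rng.normal(size=(6, 2))
        assert al.warp_to_reference(y, y) == pytest.approx(y)

    def test_duplicated_middle_element(self):
        ref = np.array([[0.0], [1.0], [2.0], [3.0]])
        pred = np.array([[0.0], [1.0], [1.0], [2.0], [3.0]])
        out = al.warp_to_reference(ref, pred)
        # min-index rule on the 4x5 optimal path: each reference point maps
        # to the first matching predicted sample.
        assert out == pytest.approx(ref)

    def test_constant_prediction_stays_constant(self, rng):
        ref = rng.normal(size=(5, 2))
        pred = np.ones((7, 2))
        out = al.warp_to_reference(ref, pred)
        assert out == pytest.approx(np.ones((5, 2)))

    def test_zero_offsets_for_identical_series(self, rng):
        y = rng.normal(size=(8, 2))
        stats = al.alignment_offsets(y, y)
        assert stats.per_point_offsets == pytest.approx(np.zeros(8))
        assert stats.sd_abs_ms == 0.0

    def test_two_bin_delay_has_modal_offset_100ms(self):
        t = np.linspace(0, 1, 30)
        bump = np.exp(-(((t - 0.4) / 0.1) ** 2))
        delayed = np.roll(bump, 2)
        delayed[:2] = bump[0]
        stats = al.alignment_offsets(bump, delayed, bin_ms=50.0)
        vals, counts = np.unique(stats.per_point_offsets, return_counts=True)
        assert abs(vals[np.argmax(counts)]) == pytest.approx(100.0)

    def test_offsets_are_bin_multiples(self, rng):
        y, z = rng.normal(size=(9, 1)), rng.normal(size=(7, 1))
        stats = al.alignment_offsets(y, z, bin_ms=50.0)
        assert np.all(np.mod(stats.per_point_offsets, 50.0) == 0)
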