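"""Basis pursuit, gradient descent on the l1 measure, Douglas-Rachford, TV."""

import itertools

import numpy as np
import pytest

from csrecon import (GradientParams, ImageMask2D, ProxParams, SamplingMask,
                     affine_projection, basis_pursuit, build_basis, cs_matrix,
                     douglas_rachford, full_mask, gen_sparse_signal,
                     gradient_reconstruct, l1_measure, lowmid_dct_mask, mse,
                     radial_fourier_mask, random_mask, soft_threshold,
                     take_measurements, tv_norm, tv_reconstruct,
                     tv_reconstruct_1d, zero_filled)
from csrecon.convex import _forward2d, reshape_1d_to_2d


class TestBasisPursuit:
    def test_one_sparse_matches_exhaustive_l0_search(self):
        n = 16
        b = build_basis("dft", n)
        gt = gen_sparse_signal(n, 1, b, seed=2, mode="complex")
        mask = random_mask(n, 0.5, 3)
        a = cs_matrix(b, mask)
        y = take_measurements(gt.data, mask)
        x = basis_pursuit(y, a)
        # oracle: the sparsest feasible point found by trying every single column
        best = None
        for j in range(n):
            col = a[:, [j]]
            c, *_ = np.linalg.lstsq(col, y, rcond=None)
            if np.linalg.norm(col @ c - y) < 1e-8:
                best = (j, c[0])
        assert best is not None
        assert np.abs(x).sum() == pytest.approx(abs(best[1]), rel=1e-5)
        assert int(np.argmax(np.abs(x))) == best[0]

    def test_square_invertible_returns_unique_solution(self, rng):
        a = rng.normal(size=(12, 12)) + 3 * np.eye(12)
        x_true = rng.normal(size=12)
        x = basis_pursuit(a @ x_true, a)
        assert np.max(np.abs(x - x_true)) < 1e-6

    def test_objective_never_beats_feasible_truth_by_margin(self):
        # the true spectrum is feasible, so BP's l1 is <= truth's l1
        n = 20
        b = build_basis("dft", n)
        for s in range(50):
            gt = gen_sparse_signal(n, 2, b, seed=s, mode="complex")
            mask = random_mask(n, 0.6, 100 + s)
            y = take_measurements(gt.data, mask)
            x = basis_pursuit(y, cs_matrix(b, mask))
            assert np.abs(x).sum() <= np.abs(gt.spectrum(n)).sum() + 1e-5


class TestGradientReconstruct:
    def test_no_missing_samples_is_identity(self):
        n = 16
        b = build_basis("dft", n)
        x = np.sin(2 * np.pi * 3 * np.arange(n) / n)
        out = gradient_reconstruct(x, full_mask(n), b)
        assert np.array_equal(out, x)

    def test_single_sinusoid_exact_recovery(self):
        n = 16
        b = build_basis("dft", n)
        x = np.cos(2 * np.pi * 3 * np.arange(n) / n)
        mask = SamplingMask(np.delete(np.arange(n), [2, 7, 9, 13]), n)
        rec = gradient_reconstruct(x[mask.available], mask, b)
        assert mse(rec.real, x) < 1e-8

    def test_available_samples_never_touched(self):
        n = 32
        b = build_basis("dft", n)
        gt = gen_sparse_signal(n, 2, b, seed=5, mode="real")
        mask = random_mask(n, 0.6, 4)
        y = take_measurements(gt.data, mask)
        rec = gradient_reconstruct(y, mask, b)
        assert np.array_equal(rec[mask.available], y)

    def test_l1_non_increasing_across_delta_stages(self):
        n = 64
        b = build_basis("dft", n)
        gt = gen_sparse_signal(n, 3, b, seed=9, mode="complex")
        mask = random_mask(n, 0.5, 6)
        y = take_measurements(gt.data, mask)
        zf_l1 = l1_measure(b.forward @ zero_filled(y, mask))
        rec, info = gradient_reconstruct(y, mask, b, return_info=True)
        stages = info["stage_l1"]
        assert len(stages) > 3
        assert all(later <= earlier + 1e-9 for earlier, later in zip(stages, stages[1:]))
        # the descent ends at or below the zero-filled starting measure
        assert stages[-1] <= zf_l1 + 1e-9


class TestProxOperators:
    def test_soft_threshold_hand_values(self):
        assert soft_threshold(np.array([2.0]), 1.0)[0] == 1.0
        assert soft_threshold(np.array([0.5, -0.3]), 0.6).tolist() == [0.0, 0.0]
        x = np.array([1.5, -2.0, 0.1])
        assert np.array_equal(soft_threshold(x, 0.0), x)

    def test_soft_threshold_shrinks_complex_modulus(self):
        z = np.array([3 + 4j])
        out = soft_threshold(z, 1.0)
        assert np.abs(out[0]) == pytest.approx(4.0)
        assert np.angle(out[0]) == pytest.approx(np.angle(z[0]))

    def test_soft_threshold_is_prox_of_l1_on_grid(self):
        # brute-force grid minimizer of 0.5||w - x||^2 + lam ||x||_1 in 2D
        w = np.array([0.9, -1.7])
        lam = 0.6
        grid = np.linspace(-3, 3, 1201)
        best = min(
            itertools.product(grid, grid),
            key=lambda p: 0.5 * np.sum((w - np.array(p)) ** 2) + lam * np.sum(np.abs(p)),
        )
        assert np.max(np.abs(soft_threshold(w, lam) - np.array(best))) < 6e-3

    def test_affine_projection_identity_and_idempotence(self, rng):
        a = rng.normal(size=(3, 8))
        y = rng.normal(size=3)
        x_feas = a.T @ np.linalg.solve(a @ a.T, y)
        assert np.max(np.abs(affine_projection(x_feas, a, y) - x_feas)) < 1e-10
        z = rng.normal(size=8)
        p1 = affine_projection(z, a, y)
        assert np.max(np.abs(a @ p1 - y)) < 1e-10
        assert np.max(np.abs(affine_projection(p1, a, y) - p1)) < 1e-10

    def test_projection_optimality_against_random_feasible_points(self, rng):
        a = rng.normal(size=(4, 10))
        y = rng.normal(size=4)
        z = rng.normal(size=10)
        p = affine_projection(z, a, y)
        null = np.linalg.svd(a)[2][4:].T  # null-space basis
        for _ in range(100):
            other = p + null @ rng.normal(size=6)
            assert np.linalg.norm(z - p) <= np.linalg.norm(z - other) + 1e-10


class TestDouglasRachford:
    def test_agrees_with_basis_pursuit(self):
        n = 16
        b = build_basis("dft", n)
        gt = gen_sparse_signal(n, 1, b, seed=12, mode="complex")
        mask = random_mask(n, 0.5, 8)
        y = take_measurements(gt.data, mask)
        a = cs_matrix(b, mask)
        xb = basis_pursuit(y, a)
        xd = douglas_rachford(y, a)
        assert abs(np.abs(xb).sum() - np.abs(xd).sum()) < 1e-4
        assert int(np.argmax(np.abs(xb))) == int(np.argmax(np.abs(xd)))

    def test_zero_measurements_give_zero(self):
        a = np.random.default_rng(0).normal(size=(4, 8))
        x = douglas_rachford(np.zeros(4), a, ProxParams(lam=1.0, mu=1.0))
        assert np.max(np.abs(x)) < 1e-8

    def test_output_is_feasible(self, rng):
        a = rng.normal(size=(6, 14))
        y = rng.normal(size=6)
        x = douglas_rachford(y, a)
        assert np.max(np.abs(a @ x - y)) < 1e-8

    def test_mu_range_enforced(self):
        with pytest.raises(ValueError):
            ProxParams(mu=2.5)


class TestTvNorm:
    def test_constant_image_zero(self):
        assert tv_norm(np.full((5, 7), 3.3)) == 0.0

    def test_two_by_two_hand_value(self):
        assert tv_norm(np.array([[0.0, 0.0], [1.0, 1.0]])) == pytest.approx(2.0)

    def test_homogeneity(self, rng):
        img = rng.normal(size=(6, 6))
        assert tv_norm(-2.5 * img) == pytest.approx(2.5 * tv_norm(img))


class TestRadialMask:
    def test_point_symmetry_exact(self):
        m = radial_fourier_mask((64, 64), 11)
        a = m.available
        i = np.arange(64)
        refl = a[(64 - i[:, None]) % 64, (64 - i[None, :]) % 64]
        assert np.array_equal(a, refl)

    def test_single_line_includes_dc(self):
        m = radial_fourier_mask((32, 32), 1)
        assert m.available[16, 16]
        assert 0 < m.fraction < 0.2

    def test_many_lines_saturate(self):
        m = radial_fourier_mask((16, 16), 400)
        assert m.fraction == 1.0

    def test_warns_on_excess_lines(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="csrecon.convex"):
            radial_fourier_mask((16, 16), 10_000)
        assert any("exceeds" in r.message for r in caplog.records)


class TestTvReconstruct:
    def test_fully_sampled_is_inverse_transform(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, (16, 16))
        mask = ImageMask2D(np.ones((16, 16), dtype=bool))
        meas = _forward2d(img, "2d-dct")
        rec = tv_reconstruct(meas[mask.available], mask, "2d-dct",
                             ProxParams(max_iter=5, tol=1e-3))
        assert np.max(np.abs(rec - img)) < 1e-8

    def test_phantom_radial_recovery_small(self):
        from csrecon import gen_phantom, psnr

        gt = gen_phantom((32, 32), 2, seed=5)
        m = radial_fourier_mask((32, 32), 14)
        meas = _forward2d(gt.data, "2d-dft")[m.available]
        rec = tv_reconstruct(meas, m, "2d-dft")
        assert psnr(rec, gt.data, peak=255.0) > 40.0

    def test_solution_tv_not_above_zero_filled_tv(self):
        from csrecon import gen_phantom

        gt = gen_phantom((32, 32), 3, seed=1)
        m = radial_fourier_mask((32, 32), 10)
        coeffs = _forward2d(gt.data, "2d-dft")
        meas = coeffs[m.available]
        zf_coeffs = np.where(m.available, coeffs, 0)
        from csrecon.convex import _inverse2d

        zf = _inverse2d(zf_coeffs, "2d-dft").real
        rec = tv_reconstruct(meas, m, "2d-dft")
        assert tv_norm(rec) <= tv_norm(zf) + 1e-6

    def test_dct_lowmid_measurements_recover_staircase(self):
        steps = np.repeat(np.array([2.0, 6.0, 0.0, 8.0]), 64).reshape(16, 16, order="F")
        m = lowmid_dct_mask((16, 16), r_low=8, fraction_mid=0.3, seed=7)
        meas = _forward2d(steps, "2d-dct")[m.available]
        rec = tv_reconstruct(meas, m, "2d-dct", ProxParams(max_iter=3000, tol=1e-10))
        assert mse(rec, steps) / np.mean(steps**2) < 1e-6


class TestTvReconstruct1d:
    def test_reshape_round_trip(self):
        rows, cols, pad = reshape_1d_to_2d(256)
        assert rows * cols == 256 and pad == 0 and {rows, cols} == {16}
        x = np.arange(256.0)
        assert np.array_equal(x.reshape(rows, cols, order="F").reshape(-1, order="F"), x)

    def test_prime_length_padded(self):
        rows, cols, pad = reshape_1d_to_2d(257)
        assert pad >= 1 and rows * cols == 257 + pad

    def test_staircase_recovery(self):
        n = 256
        rng = np.random.default_rng(0)
        steps = np.repeat(rng.integers(0, 5, 8) * 2.0, 32)
        mask = random_mask(n, 0.55, 42)  # 45% missing
        x_in = np.zeros(n)
        x_in[mask.available] = steps[mask.available]
        rec = tv_reconstruct_1d(x_in, mask)
        assert mse(rec, steps) / np.mean(steps**2) < 1e-3

    def test_available_samples_restored_bit_exactly(self):
        n = 64
        rng = np.random.default_rng(3)
        x = np.repeat(rng.uniform(0, 4, 4), 16)
        mask = random_mask(n, 0.6, 9)
        x_in = np.zeros(n)
        x_in[mask.available] = x[mask.available]
        rec = tv_reconstruct_1d(x_in, mask)
        assert np.array_equal(rec[mask.available], x[mask.available])

    def test_bad_reshape_rejected(self):
        with pytest.raises(ValueError):
            tv_reconstruct_1d(np.ones(30), random_mask(30, 0.5, 0), reshape_cols=7)
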