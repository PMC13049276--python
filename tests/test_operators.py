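"""Multi-coil forward model: adjointness, sensitivities, compression, CG-SENSE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lapsmri.codec import synth_phase_augment
from lapsmri.masks import SamplingMask, make_vd_mask_1d, make_vd_mask_2d
from lapsmri.operators import (MultiCoilKSpace, ForwardOperator, add_noise,
                               apply_adjoint, apply_forward, cg_sense,
                               coil_compress, estimate_sensitivities_lowres,
                               fft2c, ifft2c, simulate_sensitivities)
from lapsmri.phantom import make_phantom


def _rand_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def _full_mask(N):
    return SamplingMask(np.ones((N, N)), "1d", N, 1.0)


class TestSimulateSensitivities:
    def test_single_coil_is_unity(self):
        s = simulate_sensitivities(1, 16, 16)
        assert np.allclose(s, 1.0)

    @pytest.mark.parametrize("nc", [2, 4, 8, 12])
    def test_sum_of_squares_normalized(self, nc):
        s = simulate_sensitivities(nc, 24, 24, seed=nc)
        rss = np.sqrt((np.abs(s) ** 2).sum(axis=0))
        assert np.max(np.abs(rss - 1)) < 1e-6

    def test_spatial_smoothness(self):
        s = simulate_sensitivities(8, 64, 64, seed=0)
        gy = np.abs(np.diff(s, axis=1)).max()
        gx = np.abs(np.diff(s, axis=2)).max()
        # bounded per-pixel variation for the default lobe width
        assert max(gx, gy) < 0.15


class TestForwardAdjoint:
    def test_zero_maps_to_zero(self, rng):
        op = ForwardOperator(simulate_sensitivities(4, 16, 16), _full_mask(16))
        assert np.all(apply_forward(np.zeros((16, 16)), op).data == 0)
        y0 = MultiCoilKSpace(np.zeros((4, 16, 16)), _full_mask(16))
        assert np.all(apply_adjoint(y0, op) == 0)

    def test_full_single_coil_is_unitary_fft(self, rng):
        x = _rand_complex(rng, (16, 16))
        op = ForwardOperator(np.ones((1, 16, 16)), _full_mask(16))
        y = apply_forward(x, op)
        assert np.allclose(y.data[0], fft2c(x))
        assert np.linalg.norm(y.data) == pytest.approx(np.linalg.norm(x), abs=1e-10)
        assert np.allclose(apply_adjoint(y, op), ifft2c(y.data[0]))

    def test_normal_operator_is_identity_under_full_sampling(self, rng):
        x = _rand_complex(rng, (24, 24))
        op = ForwardOperator(simulate_sensitivities(6, 24, 24, seed=2),
                             _full_mask(24))
        xx = apply_adjoint(apply_forward(x, op), op)
        assert np.max(np.abs(xx - x)) < 1e-8

    def test_linearity(self, rng):
        op = ForwardOperator(simulate_sensitivities(3, 16, 16, seed=1),
                             make_vd_mask_1d(16, 16, 2, center_lines=4, seed=0))
        x1, x2 = _rand_complex(rng, (16, 16)), _rand_complex(rng, (16, 16))
        a, b = 1.7 - 0.3j, -0.6 + 2.1j
        lhs = apply_forward(a * x1 + b * x2, op).data
        rhs = a * apply_forward(x1, op).data + b * apply_forward(x2, op).data
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    @given(nc=st.integers(1, 12), kind=st.sampled_from(["1d", "2d"]),
           seed=st.integers(0, 50))
    @settings(max_examples=20, deadline=None)
    def test_adjoint_dot_product_identity(self, nc, kind, seed):
        N = 16
        rng = np.random.default_rng(seed)
        if kind == "1d":
            mask = make_vd_mask_1d(N, N, 2, center_lines=4, seed=seed)
        else:
            mask = make_vd_mask_2d(N, N, 3, center_block=4, seed=seed)
        op = ForwardOperator(simulate_sensitivities(nc, N, N, seed=seed), mask)
        x = _rand_complex(rng, (N, N))
        u = _rand_complex(rng, (nc, N, N)) * mask.mask[None]
        lhs = np.vdot(u, apply_forward(x, op).data)
        rhs = np.vdot(apply_adjoint(MultiCoilKSpace(u, mask), op), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_shape_mismatch_rejected(self, rng):
        op = ForwardOperator(simulate_sensitivities(2, 16, 16), _full_mask(16))
        with pytest.raises(ValueError):
            apply_forward(np.zeros((8, 8)), op)


class TestSensitivityEstimation:
    def test_recovery_of_simulator_maps(self):
        """Relative maps recovered within 5% NRMSE on the bright support."""
        N = 64
        smaps = simulate_sensitivities(8, N, N, seed=1)
        ph = synth_phase_augment(make_phantom(N, N, seed=3), seed=4)
        mask = make_vd_mask_1d(N, N, 2, center_lines=24, seed=2)
        y = apply_forward(ph, ForwardOperator(smaps, mask))
        est = estimate_sensitivities_lowres(y, center_size=24)
        sup = np.abs(ph) > 0.5 * np.abs(ph).max()
        # the estimate carries the image phase; compare coil ratios
        ref_rel = smaps * np.conj(smaps[0]) / np.maximum(np.abs(smaps[0]), 1e-9)
        est_rel = est * np.conj(est[0]) / np.maximum(np.abs(est[0]), 1e-9)
        err = np.linalg.norm((est_rel - ref_rel)[:, sup]) \
            / np.linalg.norm(ref_rel[:, sup])
        assert err < 0.05

    def test_single_coil_unit_modulus(self):
        N = 32
        ph = synth_phase_augment(make_phantom(N, N, seed=1), seed=2)
        y = apply_forward(ph, ForwardOperator(np.ones((1, N, N)), _full_mask(N)))
        est = estimate_sensitivities_lowres(y, center_size=16)
        sup = np.abs(est[0]) > 0
        assert np.allclose(np.abs(est[0][sup]), 1.0, atol=1e-9)

    def test_sum_of_squares_on_output(self):
        N = 32
        smaps = simulate_sensitivities(4, N, N, seed=5)
        ph = synth_phase_augment(make_phantom(N, N, seed=6), seed=7)
        y = apply_forward(ph, ForwardOperator(smaps, _full_mask(N)))
        est = estimate_sensitivities_lowres(y, center_size=16)
        rss = np.sqrt((np.abs(est) ** 2).sum(axis=0))
        sup = rss > 0
        assert np.allclose(rss[sup], 1.0, atol=1e-9)

    def test_unsampled_center_rejected(self):
        N = 32
        mask = np.zeros((N, N), dtype=bool)
        mask[:, ::4] = True
        sm = SamplingMask(mask, "1d", 0, 4.0)
        y = MultiCoilKSpace(np.ones((2, N, N)) * mask, sm)
        with pytest.raises(ValueError, match="not fully sampled"):
            estimate_sensitivities_lowres(y, center_size=8)


class TestCoilCompress:
    def test_rank_one_data_keeps_single_coil(self, rng):
        base = _rand_complex(rng, (32, 32))
        weights = np.array([1.0, 0.5 + 0.2j, -0.3j])
        y = MultiCoilKSpace(weights[:, None, None] * base, _full_mask(32))
        yc, P = coil_compress(y, energy=0.95)
        assert yc.n_coils == 1

    def test_energy_fraction_retained(self, rng):
        y = MultiCoilKSpace(_rand_complex(rng, (8, 16, 16)), _full_mask(16))
        yc, P = coil_compress(y, energy=0.95)
        s_full = np.linalg.svd(y.data.reshape(8, -1), compute_uv=False)
        s_kept = np.linalg.svd(yc.data.reshape(yc.n_coils, -1), compute_uv=False)
        assert np.sum(s_kept ** 2) / np.sum(s_full ** 2) >= 0.95

    def test_cg_sense_stable_under_compression(self):
        N = 64
        smaps = simulate_sensitivities(8, N, N, seed=0)
        ph = synth_phase_augment(make_phantom(N, N, seed=1), seed=2)
        mask = make_vd_mask_1d(N, N, 2, center_lines=12, seed=3)
        op = ForwardOperator(smaps, mask)
        y = apply_forward(ph, op)
        x_full = cg_sense(y, op, lam=1e-3, n_iter=15)
        yc, P = coil_compress(y, energy=0.95)
        smaps_c = (P @ smaps.reshape(8, -1)).reshape(-1, N, N)
        x_comp = cg_sense(yc, ForwardOperator(smaps_c, mask), lam=1e-3, n_iter=15)
        rel = np.linalg.norm(x_comp - x_full) / np.linalg.norm(x_full)
        assert rel < 0.02

    def test_invalid_energy_rejected(self, rng):
        y = MultiCoilKSpace(_rand_complex(rng, (2, 8, 8)), _full_mask(8))
        with pytest.raises(ValueError):
            coil_compress(y, energy=1.5)


class TestCGSense:
    def test_full_sampling_inverts_forward(self, rng):
        N = 32
        op = ForwardOperator(simulate_sensitivities(4, N, N, seed=1), _full_mask(N))
        x = _rand_complex(rng, (N, N))
        xr = cg_sense(apply_forward(x, op), op, lam=0.0, n_iter=10)
        assert np.linalg.norm(xr - x) / np.linalg.norm(x) <= 1e-3

    def test_large_lambda_shrinks_solution(self, rng):
        N = 16
        op = ForwardOperator(simulate_sensitivities(2, N, N, seed=2), _full_mask(N))
        y = apply_forward(_rand_complex(rng, (N, N)), op)
        x = cg_sense(y, op, lam=1e6, n_iter=10)
        assert np.linalg.norm(x) < 1e-3

    def test_residual_nonincreasing(self, rng):
        N = 32
        mask = make_vd_mask_1d(N, N, 3, center_lines=8, seed=1)
        op = ForwardOperator(simulate_sensitivities(4, N, N, seed=3), mask)
        y = apply_forward(_rand_complex(rng, (N, N)), op)
        b = apply_adjoint(y, op)
        res = []
        for n in range(1, 8):
            x = cg_sense(y, op, lam=1e-2, n_iter=n)
            r = b - (apply_adjoint(apply_forward(x, op), op) + 1e-2 * x)
            res.append(np.linalg.norm(r))
        assert all(res[i + 1] <= res[i] + 1e-12 for i in range(len(res) - 1))


class TestAddNoise:
    def test_zero_sigma_identity(self, rng):
        y = MultiCoilKSpace(_rand_complex(rng, (2, 8, 8)), _full_mask(8))
        assert np.array_equal(add_noise(y, 0.0, seed=1).data, y.data)

    def test_variance_at_sampled_points(self):
        N = 128
        mask = _full_mask(N)
        y = MultiCoilKSpace(np.zeros((8, N, N)), mask)
        yn = add_noise(y, sigma=0.3, seed=0)
        v = np.mean(np.abs(yn.data) ** 2)
        assert v == pytest.approx(2 * 0.3 ** 2, rel=0.02)

    def test_unsampled_entries_stay_zero(self, rng):
        N = 32
        mask = make_vd_mask_1d(N, N, 4, center_lines=4, seed=0)
        y = MultiCoilKSpace(_rand_complex(rng, (2, N, N)) * mask.mask, mask)
        yn = add_noise(y, sigma=1.0, seed=2)
        assert np.all(yn.data[:, ~mask.mask] == 0)
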