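"""Posterior samplers: DC gradients, LDPS, CAPS/LAPS plumbing, output DC."""

import numpy as np
import pytest

from lapsmri.codec import decode, encode
from lapsmri.masks import SamplingMask, make_vd_mask_1d
from lapsmri.operators import (MultiCoilKSpace, ForwardOperator, apply_forward,
                               simulate_sensitivities)
from lapsmri.phantom import make_pair
from lapsmri.samplers import (ReconConfig, average_samples, caps_recon,
                              dc_gradient_latent, hot_started_sample,
                              laps_recon, ldps_sample, output_dc)
from lapsmri.schedule import ddim_sample, gaussian_oracle, tweedie_denoise


def _operator(rng, N=16, nc=4, R=2.0, seed=0):
    mask = make_vd_mask_1d(N, N, R, center_lines=4, seed=seed) if R > 1 else \
        SamplingMask(np.ones((N, N)), "1d", N, 1.0)
    smaps = simulate_sensitivities(nc, N, N, seed=seed)
    return ForwardOperator(smaps, mask)


class TestDCGradient:
    def test_zero_at_stationary_point(self, schedule, ident, rng):
        op = _operator(rng)
        o = gaussian_oracle(schedule)
        zt = rng.standard_normal((16, 16, 2))
        t = 300
        z0h = tweedie_denoise(zt, t, o, schedule)
        y = apply_forward(decode(z0h, ident), op)
        g = dc_gradient_latent(zt, t, y, op, ident, o, schedule)
        assert np.max(np.abs(g)) < 1e-10

    def test_matches_linear_gaussian_closed_form(self, schedule, ident, rng):
        """Identity codec + analytic model: the whole pipeline is linear, so
        the gradient is 2 * J^T A^H (A J z... ) with J = sqrt(ab) I."""
        op = _operator(rng, seed=1)
        o = gaussian_oracle(schedule)
        t = 400
        ab = schedule.alpha_bar[t]
        zt = rng.standard_normal((16, 16, 2))
        x_target = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = apply_forward(x_target, op)
        g = dc_gradient_latent(zt, t, y, op, ident, o, schedule)
        # hand-derived: z0hat = sqrt(ab) zt; r = y - A z0hat;
        # dL/dzt = -2 sqrt(ab) real_view(A^H r)
        from lapsmri.operators import apply_adjoint
        z0h = np.sqrt(ab) * zt
        x = z0h[..., 0] + 1j * z0h[..., 1]
        r = y.data - apply_forward(x, op).data
        ahr = apply_adjoint(MultiCoilKSpace(r, y.mask), op)
        expect = -2.0 * np.sqrt(ab) * np.stack([ahr.real, ahr.imag], axis=-1)
        assert np.max(np.abs(g - expect)) < 1e-8

    def test_finite_difference_agreement(self, schedule, codec64, toy_model, rng):
        p = make_pair(seed=1, N=64, n_coils=4,
                      mask_spec={"kind": "1d", "R": 4, "center": 8})
        op = ForwardOperator(p.smaps, p.kspace.mask)
        zt = rng.standard_normal((16, 16, 4))
        t = 500
        g = dc_gradient_latent(zt, t, p.kspace, op, codec64, toy_model, schedule)

        def loss(z):
            ab = schedule.alpha_bar[t]
            z0 = (z - np.sqrt(1 - ab) * toy_model.eps(z, t)) / np.sqrt(ab)
            r = p.kspace.data - apply_forward(decode(z0, codec64), op).data
            return float(np.sum(np.abs(r) ** 2))

        direction = rng.standard_normal(zt.shape)
        direction /= np.linalg.norm(direction)
        eps = 1e-5
        fd = (loss(zt + eps * direction) - loss(zt - eps * direction)) / (2 * eps)
        assert fd == pytest.approx(float(np.sum(g * direction)), rel=1e-3)


class TestLDPS:
    def test_nopt_zero_equals_unconditional_ddim(self, schedule, ident, rng):
        op = _operator(rng, seed=2)
        o = gaussian_oracle(schedule)
        z = rng.standard_normal((16, 16, 2))
        y = apply_forward(rng.standard_normal((16, 16)) + 0j, op)
        cfg = ReconConfig(n_step=25, n_opt=0, n_avg=1)
        out = ldps_sample(y, op, z.copy(), 600, ident, o, schedule, cfg)
        ref = ddim_sample(z.copy(), 600, o, schedule, n_step=25)
        assert np.array_equal(out, ref)

    def test_wellposed_limit_recovers_target(self, schedule, ident, rng):
        """Fully sampled, noiseless: LDPS converges to the measurement."""
        op = _operator(rng, N=16, nc=4, R=1.0, seed=3)
        x_true = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = apply_forward(x_true, op)
        o = gaussian_oracle(schedule)
        cfg = ReconConfig(n_step=50, n_opt=10, n_avg=1, lr=5e-2, n_cg_out=6,
                          lam_dc=1e-3)
        x = hot_started_sample(y, op, encode(x_true, ident), 200, ident, o,
                               schedule, cfg, sample_seed=0)
        assert np.linalg.norm(x - x_true) / np.linalg.norm(x_true) <= 1e-2

    def test_dc_residual_trend_nonincreasing(self, schedule, ident, rng):
        op = _operator(rng, seed=4)
        x_true = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = apply_forward(x_true, op)
        o = gaussian_oracle(schedule)
        cfg = ReconConfig(n_step=20, n_opt=8, n_avg=1, lr=5e-2)
        diag = {}
        ldps_sample(y, op, rng.standard_normal((16, 16, 2)), 1000, ident, o,
                    schedule, cfg, diagnostics=diag)
        # within each diffusion step the inner DC loss trend decreases
        for inner in diag["dc_residuals"]:
            assert inner[-1] <= inner[0] + 1e-9


class TestOutputDC:
    def test_large_lambda_keeps_input(self, schedule, rng):
        op = _operator(rng, seed=5)
        x_dec = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = apply_forward(rng.standard_normal((16, 16)) + 0j, op)
        out = output_dc(x_dec, y, op, lam_dc=1e8, n_cg=6)
        assert np.linalg.norm(out - x_dec) / np.linalg.norm(x_dec) < 1e-3

    def test_exact_dc_limit(self, rng):
        op = _operator(rng, N=16, nc=4, R=1.0, seed=6)
        x_true = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = apply_forward(x_true, op)
        out = output_dc(x_true + 0.3 * rng.standard_normal((16, 16)), y, op,
                        lam_dc=0.0, n_cg=10)
        assert np.linalg.norm(out - x_true) / np.linalg.norm(x_true) < 1e-3

    def test_objective_nonincreasing(self, rng):
        op = _operator(rng, seed=7)
        x_true = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        y = apply_forward(x_true, op)
        x_dec = x_true + 0.5 * rng.standard_normal((16, 16))
        lam = 1e-2

        def obj(x):
            r = y.data - apply_forward(x, op).data
            return np.sum(np.abs(r) ** 2) + lam * np.sum(np.abs(x - x_dec) ** 2)

        vals = [obj(output_dc(x_dec, y, op, lam_dc=lam, n_cg=n))
                for n in range(1, 7)]
        assert all(vals[i + 1] <= vals[i] + 1e-9 for i in range(len(vals) - 1))


class TestAveraging:
    def test_identical_samples(self, rng):
        s = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        assert np.allclose(average_samples([s, s, s]), s)

    def test_single_sample_identity(self, rng):
        s = rng.standard_normal((4, 4)) + 0j
        assert np.array_equal(average_samples([s]), s)

    def test_triangle_inequality(self, rng):
        samples = [rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
                   for _ in range(4)]
        cm = np.abs(average_samples(samples, "complex"))
        mm = average_samples(samples, "magnitude")
        assert np.all(cm <= mm + 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_samples([])


class TestReconFrontEnds:
    def test_config_defaults_match_reference_operating_point(self):
        cfg = ReconConfig()
        assert (cfg.n_opt, cfg.n_step, cfg.n_avg, cfg.n_cg_out) == (10, 100, 4, 6)
        assert ReconConfig.caps().t_p == 200
        fast = ReconConfig.fast_init()
        assert (fast.t_p, fast.n_opt, fast.n_step, fast.n_avg) == (200, 5, 80, 1)

    def test_caps_records_tp(self, schedule, codec64, toy_model):
        p = make_pair(seed=21, N=64, n_coils=4,
                      mask_spec={"kind": "1d", "R": 4, "center": 8})
        op = ForwardOperator(p.smaps, p.kspace.mask)
        res = caps_recon(p.kspace, op, codec64, toy_model, schedule,
                         ReconConfig.caps(n_step=20, n_opt=2, n_avg=1))
        assert res.t_p == 200
        assert len(res.samples) == 1

    def test_laps_requires_prior(self, schedule, codec64, toy_model):
        p = make_pair(seed=22, N=64, n_coils=4,
                      mask_spec={"kind": "1d", "R": 4, "center": 8})
        op = ForwardOperator(p.smaps, p.kspace.mask)
        with pytest.raises(ValueError, match="caps_recon"):
            laps_recon(p.kspace, op, None, codec64, toy_model, schedule)

    def test_final_image_is_average_of_samples(self, schedule, codec64, toy_model):
        p = make_pair(seed=23, N=64, n_coils=4,
                      mask_spec={"kind": "1d", "R": 4, "center": 8})
        op = ForwardOperator(p.smaps, p.kspace.mask)
        res = caps_recon(p.kspace, op, codec64, toy_model, schedule,
                         ReconConfig.caps(n_step=20, n_opt=2, n_avg=3))
        assert np.allclose(res.image, np.mean(res.samples, axis=0))

    def test_full_run_bit_reproducible(self, schedule, codec64, toy_model):
        p = make_pair(seed=24, N=64, change_level="low", n_coils=4,
                      mask_spec={"kind": "1d", "R": 4, "center": 8})
        op = ForwardOperator(p.smaps, p.kspace.mask)
        cfg = ReconConfig(n_step=20, n_opt=2, n_avg=2, seed=11)
        a = laps_recon(p.kspace, op, p.prior_mag, codec64, toy_model, schedule,
                       None, cfg)
        b = laps_recon(p.kspace, op, p.prior_mag, codec64, toy_model, schedule,
                       None, cfg)
        assert np.array_equal(a.image, b.image)
        assert a.t_p == b.t_p
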