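"""Jones decomposition, degeneracy classes and Bayesian MAP inference."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrepol.fields import default_calibration_states
from fibrepol.fibre import make_target
from fibrepol.polarimetry import (PolarimetricParams, PriorSpec,
                                  jones_forward, equivalence_class,
                                  canonicalise, log_posterior, infer_pixel,
                                  infer_joint, infer_map,
                                  sample_synthetic_pixels,
                                  axis_posterior_spread, _circ_dist)
from conftest import class_aware_errors

U3 = default_calibration_states()


def random_params(rng):
    return PolarimetricParams(
        rng.uniform(-np.pi / 2, np.pi / 2) * 0.999,
        rng.uniform(-np.pi, np.pi), rng.uniform(-np.pi, np.pi),
        rng.uniform(-1, 1), rng.uniform(-np.pi / 2, np.pi / 2) * 0.999)


def noisy_observation(p, rng, sigma, n_states=3):
    V = U3[:n_states] @ jones_forward(p).T
    noise = (rng.normal(size=(n_states, 2))
             + 1j * rng.normal(size=(n_states, 2))) * sigma / np.sqrt(2)
    return U3[:n_states], V + noise


class TestJonesForward:
    def test_null_parameters_give_identity(self):
        p = PolarimetricParams(0.7, 0.0, 0.0, 0.0, -0.3)
        np.testing.assert_allclose(jones_forward(p), np.eye(2), atol=1e-14)

    def test_full_polariser_on_h_axis(self):
        p = PolarimetricParams(0.0, 0.0, 0.0, 1.0, 0.0)
        np.testing.assert_allclose(jones_forward(p), np.diag([2.0, 0.0]),
                                   atol=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            jones_forward(PolarimetricParams(0.0, 4.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            jones_forward(PolarimetricParams(0.0, 0.0, 0.0, 1.5, 0.0))


class TestEquivalenceClass:
    def test_eight_members_same_jones_matrix(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(200):
            p = random_params(rng)
            J = jones_forward(p)
            members = equivalence_class(p)
            assert len(members) == 8
            for m in members:
                worst = max(worst, np.abs(jones_forward(m) - J).max())
        assert worst < 1e-10

    def test_members_distinct_for_generic_point(self):
        p = PolarimetricParams(0.3, 1.1, 0.4, 0.5, -0.2)
        arrays = [tuple(np.round(m.as_array(), 9))
                  for m in equivalence_class(p)]
        assert len(set(arrays)) == 8

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_canonicalise_idempotent_and_jones_preserving(self, seed):
        p = random_params(np.random.default_rng(seed))
        c = canonicalise(p)
        c2 = canonicalise(c)
        np.testing.assert_allclose(c2.as_array(), c.as_array(), atol=1e-12)
        assert np.abs(jones_forward(c, validate=False)
                      - jones_forward(p, validate=False)).max() < 1e-10

    def test_all_members_canonicalise_to_same_point(self):
        p = PolarimetricParams(-0.8, 2.0, -1.0, 0.6, 1.2)
        canon = [canonicalise(m).as_array() for m in equivalence_class(p)]
        for c in canon[1:]:
            np.testing.assert_allclose(c, canon[0], atol=1e-12)


class TestLogPosterior:
    def test_noiseless_truth_beats_parameter_grid(self):
        rng = np.random.default_rng(1)
        p = PolarimetricParams(0.5, 1.2, 0.3, 0.4, -0.7)
        U, V = U3, U3 @ jones_forward(p).T
        prior = PriorSpec(kappa_delta=0.0, D_variance=1e6)  # likelihood only
        lp_true = log_posterior(p, U, V, prior)
        for _ in range(200):
            q = random_params(rng)
            assert log_posterior(q, U, V, prior) <= lp_true + 1e-9

    def test_sigma_doubling_scales_exponent_by_four(self):
        rng = np.random.default_rng(2)
        p = random_params(rng)
        U, V = noisy_observation(p, rng, 0.3)
        n = U.shape[0]

        def exponent(sigma):
            prior = PriorSpec(sigma=sigma)
            lp = log_posterior(p, U, V, prior)
            # strip the normalisation and prior terms, leaving -r^2/sigma^2
            return lp + 2 * n * np.log(np.pi * sigma ** 2) \
                - log_posterior(p, U, V, prior) * 0 \
                - (log_posterior(p, U, V, replace(prior, sigma=1e9))
                   + 2 * n * np.log(np.pi * 1e18))

        assert abs(exponent(0.2) / exponent(0.4) - 4.0) < 1e-6

    def test_flat_axis_prior_constant_across_theta_phi(self):
        prior = PriorSpec(kappa_axes=0.0)
        rng = np.random.default_rng(3)
        p = random_params(rng)
        U, V = noisy_observation(p, rng, 0.2)
        base = log_posterior(p, U, V, prior)
        # prior contribution must not vary with the axis angle; compensate
        # the likelihood by transforming data consistently is impractical,
        # so compare the prior term directly
        from fibrepol.polarimetry import _log_prior
        vals = [_log_prior(replace(p, theta_phi=t), prior)
                for t in np.linspace(-1.5, 1.5, 7)]
        assert np.ptp(vals) < 1e-12
        assert np.isfinite(base)

    def test_gauge_invariance_under_global_phase(self):
        rng = np.random.default_rng(4)
        p = random_params(rng)
        U, V = noisy_observation(p, rng, 0.1)
        prior = PriorSpec()
        lp0 = log_posterior(p, U, V, prior)
        for alpha in (0.3, 1.7, -2.2):
            lp = log_posterior(p, U, V * np.exp(1j * alpha), prior)
            assert abs(lp - lp0) < 1e-9

    def test_minimum_two_states_required(self):
        p = PolarimetricParams(0.1, 0.5, 0.0, 0.2, 0.0)
        with pytest.raises(ValueError, match="two polarisation states"):
            log_posterior(p, U3[:1], (U3 @ jones_forward(p).T)[:1],
                          PriorSpec())


class TestInferPixel:
    def test_noiseless_recovery_within_class(self):
        # likelihood-dominated configuration: noiseless data, flat priors
        rng = np.random.default_rng(5)
        prior = PriorSpec(sigma=0.01, kappa_delta=0.0, D_variance=1e6)
        for p in sample_synthetic_pixels(25, rng):
            V = U3 @ jones_forward(p).T
            out = infer_pixel(U3, V, prior)
            errs = class_aware_errors(out["params"], p)
            assert errs.max() < 1e-2

    def test_map_estimates_gauge_invariant(self):
        rng = np.random.default_rng(6)
        p = sample_synthetic_pixels(1, rng)[0]
        U, V = noisy_observation(p, rng, 0.2)
        prior = PriorSpec(sigma=0.2)
        a = infer_pixel(U, V, prior)["params"].as_array()
        b = infer_pixel(U, V * np.exp(0.9j), prior)["params"].as_array()
        assert np.abs(a - b).max() < 1e-6

    def test_vanishing_retardance_leaves_axis_unconstrained(self):
        p0 = PolarimetricParams(0.7, 0.0, 0.0, 0.3, 0.2)
        V = U3 @ jones_forward(p0).T
        prior = PriorSpec(sigma=0.05)
        out = infer_pixel(U3, V, prior)
        assert abs(out["params"].phi) < 0.05
        spread = axis_posterior_spread(U3, V, prior, out["params_raw"])
        assert spread > 1.0

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="two polarisation states"):
            infer_pixel(U3[:1], U3[:1], PriorSpec())

    def test_noise_recovery_within_consistency_bands(self):
        # 500 prior-matched pixels at the default noise level sigma = 0.4
        rng = np.random.default_rng(2024)
        prior = PriorSpec()
        dphi, dD = [], []
        for p in sample_synthetic_pixels(500, rng):
            U, V = noisy_observation(p, rng, prior.sigma)
            out = infer_pixel(U, V, prior)
            e = class_aware_errors(out["params"], p)
            dphi.append(e[1])
            dD.append(e[3])
        dphi, dD = np.array(dphi), np.array(dD)
        assert np.sqrt((dD ** 2).mean()) <= 0.2
        assert np.median(dphi) <= 0.4
        assert np.sqrt((dphi ** 2).mean()) <= 0.55

    def test_three_states_beat_two(self):
        rng = np.random.default_rng(11)
        sigma = 0.2
        prior = PriorSpec(sigma=sigma)
        err3, err2 = [], []
        for p in sample_synthetic_pixels(150, rng):
            U, V = noisy_observation(p, rng, sigma)
            err3.append(np.linalg.norm(class_aware_errors(
                infer_pixel(U, V, prior)["params"], p)))
            err2.append(np.linalg.norm(class_aware_errors(
                infer_pixel(U[:2], V[:2], prior)["params"], p)))
        assert np.median(err3) < np.median(err2)


class TestInferJoint:
    PITCH = 9.0

    def _coords(self, ny=3, nx=5):
        xs, ys = np.meshgrid(np.arange(nx) * self.PITCH,
                             np.arange(ny) * self.PITCH)
        return np.column_stack([xs.ravel(), ys.ravel()])

    def test_tilt_free_matches_per_pixel(self):
        p = PolarimetricParams(0.5, 1.3, 0.0, 0.4, -0.6)
        V = U3 @ jones_forward(p).T
        prior = PriorSpec(sigma=0.05)
        coords = self._coords()
        out = infer_joint([U3] * 15, [V] * 15, coords, prior)
        pp = infer_pixel(U3, V, prior)["params"]
        pj = out["params"][0]
        assert _circ_dist(pj.theta_phi, pp.theta_phi, np.pi) < 1e-2
        assert _circ_dist(pj.phi, pp.phi, 2 * np.pi) < 1e-2
        assert abs(pj.D - pp.D) < 1e-2
        assert _circ_dist(pj.theta_D, pp.theta_D, np.pi) < 1e-2
        assert np.hypot(*out["ramp"]) < 1e-3

    def test_arm_tilt_gradient_suppressed_tenfold(self):
        # quarter-wave retarder at 45 deg with a linear inter-arm phase ramp
        p = PolarimetricParams(np.pi / 4, np.pi / 2, 0.0, 0.0, 0.0)
        J = jones_forward(p)
        t = 0.02   # rad/µm
        coords = self._coords()
        U_list, V_list, phis_pp = [], [], []
        prior = PriorSpec()
        A = np.column_stack([coords, np.ones(len(coords))])
        for (x, y) in coords:
            ramp = np.diag([1.0, np.exp(1j * t * x)])
            V = U3 @ (ramp @ J).T
            U_list.append(U3)
            V_list.append(V)
            phis_pp.append(infer_pixel(U3, V, prior)["params"].phi)
        sol, *_ = np.linalg.lstsq(A, np.unwrap(phis_pp), rcond=None)
        grad_pp = np.hypot(sol[0], sol[1])
        out = infer_joint(U_list, V_list, coords, prior)
        grad_joint = out["tilt"]
        assert grad_pp > t / 10          # artefact visible per pixel
        assert grad_pp / max(grad_joint, 1e-12) >= 10

    def test_neighbourhood_size_default_is_fifteen(self):
        assert PriorSpec().R == 15


class TestInferMap:
    def _run_map(self, target_kind, ny=3, nx=10, bar_cols=6, phi0=np.pi / 2):
        # single wide bar covering the first ``bar_cols`` columns so the
        # foreground/background edge coincides with a tile boundary
        w = bar_cols * 9.0
        centre_x = -(nx / 2 - bar_cols / 2) * 9.0
        sample = make_target(target_kind, (ny, nx), pixel_pitch=9.0,
                             bar_width=w, n_bars=1, center=(centre_x, 0.0),
                             phi0=phi0)
        U_img = np.zeros((ny, nx, 3, 2), complex)
        V_img = np.zeros((ny, nx, 3, 2), complex)
        for iy in range(ny):
            for ix in range(nx):
                J = sample.jones[iy, ix] * sample.transmittance[iy, ix]
                U_img[iy, ix] = U3
                V_img[iy, ix] = U3 @ J.T
        return infer_map(U_img, V_img, PriorSpec(sigma=0.05), pixel_pitch=9.0)

    def test_diattenuation_target_contrast_in_theta_d(self):
        maps = self._run_map("diattenuation_bars")
        fg = maps["theta_D"][:, :6]
        bg = maps["theta_D"][:, 6:]
        # foreground polariser axis 0, background pi/2 (mod pi)
        assert np.all(np.abs(np.vectorize(
            lambda v: _circ_dist(v, 0.0, np.pi))(fg)) < 0.1)
        assert np.all(np.abs(np.vectorize(
            lambda v: _circ_dist(v, np.pi / 2, np.pi))(bg)) < 0.1)
        assert np.abs(maps["D"]).min() > 0.9
        assert not maps["theta_D_low_confidence"].any()

    def test_birefringent_target_contrast_in_theta_phi(self):
        maps = self._run_map("birefringent_bars")
        fg = maps["theta_phi"][:, :6]
        bg = maps["theta_phi"][:, 6:]
        # each region uniform; the regions differ by the encoded 45 deg
        # (comparisons modulo the degeneracy class representative)
        assert max(_circ_dist(v, fg.ravel()[0], np.pi)
                   for v in fg.ravel()) < 0.05
        assert max(_circ_dist(v, bg.ravel()[0], np.pi)
                   for v in bg.ravel()) < 0.05
        assert abs(_circ_dist(fg.ravel()[0], bg.ravel()[0], np.pi)
                   - np.pi / 4) < 0.1
        # other parameter maps carry no structure (|phi| absorbs the class
        # sign flip between representatives)
        assert np.ptp(np.abs(maps["phi"])) < 0.1
        assert np.abs(maps["D"]).max() < 0.1

    def test_flat_slide_gives_flat_maps(self):
        maps = self._run_map("flat_slide")
        assert np.abs(maps["phi"]).max() < 0.05
        assert np.abs(maps["D"]).max() < 0.1
        assert np.ptp(maps["delta"]) < 1e-9   # delta fixed at 0 by the model
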