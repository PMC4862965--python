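"""Closed-loop filter: free energy, perception, action, simulation."""

import numpy as np
import pytest
from scipy.linalg import expm

from pursuitdcm.agent import PursuitParams
from pursuitdcm.inference_loop import (
    FilterSettings,
    GenerativeModel,
    NumericalInstabilityError,
    _FilterContext,
    action_step,
    free_energy,
    perception_step,
    pursuit_model,
    run_filter,
    simulate_pursuit,
)
from pursuitdcm.stimulus import StimulusConfig


def linear_model(ln_pi_s=8.0, ln_pi_x=6.0):
    """Damped oscillator with position observation (noise-free)."""
    A = np.array([[0.0, 1.0], [-1.0, -0.8]])
    C = np.array([[1.0, 0.0]])
    return GenerativeModel(
        n_states=2, n_causes=1, n_obs=1,
        f=lambda x, v, t: A @ x,
        fx=lambda x, v, t: A,
        fv=lambda x, v, t: np.zeros((2, 1)),
        g=lambda x: C @ x,
        gx=lambda x: C,
        eta=lambda t, order: np.zeros(order),
        ln_pi_s=ln_pi_s, ln_pi_x=ln_pi_x, ln_pi_v=-4.0,
    ), A, C


class TestFreeEnergy:
    def test_zero_errors_give_zero_free_energy(self):
        model, A, C = linear_model()
        settings = FilterSettings()
        ctx = _FilterContext(model, settings)
        mu = np.zeros(ctx.N)
        s = np.zeros((settings.order_s, 1))
        out = free_energy(mu, s, model, settings)
        assert out.F == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out.grad, 0.0)

    def test_sensory_term_scales_with_precision(self):
        model, *_ = linear_model(ln_pi_s=2.0, ln_pi_x=-20.0)
        model2, *_ = linear_model(ln_pi_s=2.0 + np.log(3), ln_pi_x=-20.0)
        settings = FilterSettings(order_x=2, order_v=1, order_s=1)
        mu = np.zeros(2 * 2 + 1)
        s = np.array([[0.5]])
        F1 = free_energy(mu, s, model, settings).F
        F2 = free_energy(mu, s, model2, settings).F
        assert F2 == pytest.approx(3.0 * F1, rel=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        params = PursuitParams()
        cfg = StimulusConfig()
        model = pursuit_model(params, cfg)
        settings = FilterSettings()
        ctx = _FilterContext(model, settings)
        mu = rng.normal(0, 0.3, ctx.N)
        s = rng.normal(0, 0.3, (settings.order_s, 18))
        out = ctx.evaluate(mu, s, 0.3)
        eps = 1e-6
        fd = np.empty(ctx.N)
        for i in range(ctx.N):
            d = np.zeros(ctx.N)
            d[i] = eps
            fd[i] = (ctx.evaluate(mu + d, s, 0.3).F
                     - ctx.evaluate(mu - d, s, 0.3).F) / (2 * eps)
        # the linearisation treats the occluder state inside the
        # attraction weights as locally constant, so the target-belief
        # coordinate carries a small systematic difference
        assert np.allclose(out.grad, fd, rtol=1e-2, atol=5e-2)

    def test_nonfinite_inputs_rejected(self):
        model, *_ = linear_model()
        with pytest.raises(ValueError):
            free_energy(np.full(5, np.nan), np.zeros((2, 1)), model)


class TestPerceptionStep:
    def test_free_flight_follows_generalized_motion(self):
        # with no gradients, beliefs follow D mu: position advances by
        # its own believed velocity
        model, *_ = linear_model(ln_pi_s=-30.0, ln_pi_x=-30.0)
        settings = FilterSettings(order_x=2, order_v=1, order_s=1)
        ctx = _FilterContext(model, settings)
        mu = np.array([1.0, 0.5, 0.3, -0.2, 0.0])  # x^(0), x^(1), v
        out = free_energy(mu, np.zeros((1, 1)), model, settings)
        new = perception_step(mu, out, dt=0.01, ctx=ctx)
        assert new[0] == pytest.approx(1.0 + 0.01 * 0.3, abs=1e-4)
        assert new[1] == pytest.approx(0.5 + 0.01 * (-0.2), abs=1e-4)

    def test_divergence_raises_named_error(self):
        model, *_ = linear_model()
        settings = FilterSettings(divergence_norm=1e-6)
        ctx = _FilterContext(model, settings)
        mu = np.ones(ctx.N)
        out = ctx.evaluate(mu, np.zeros((2, 1)), 0.0)
        with pytest.raises(NumericalInstabilityError):
            perception_step(mu, out, 0.01, ctx)

    def test_first_order_convergence_in_dt(self):
        # halving dt changes the one-step-per-sample trajectory by O(dt)
        model, A, C = linear_model()
        dt = 0.02
        n = 400
        t = np.arange(2 * n) * dt / 2
        y = np.cos(t)[:, None]
        tr_f = run_filter(model, y[::2], dt)
        tr_h = run_filter(model, y, dt / 2)
        err = np.abs(tr_f[-1, 0] - tr_h[-1, 0])
        tr_q = run_filter(model, np.cos(np.arange(4 * n) * dt / 4)[:, None],
                          dt / 4)
        err2 = np.abs(tr_h[-1, 0] - tr_q[-1, 0])
        assert err2 < err  # refining the step shrinks the difference


class TestKalmanOracle:
    def test_steady_state_matches_kalman_filter(self):
        """Generalized filtering of a noiseless linear-Gaussian system
        agrees with the (here exact) Kalman filter to within 2% RMS."""
        model, A, C = linear_model()
        dt = 0.01
        n = 2000
        Ad = expm(A * dt)
        x = np.array([1.0, 0.0])
        X = np.empty((n, 2))
        for i in range(n):
            X[i] = x
            x = Ad @ x
        y = X[:, :1]
        trace = run_filter(model, y, dt)
        # Kalman oracle on the discretized system
        Q, R = 1e-5 * np.eye(2), np.array([[1e-5]])
        P = np.eye(2)
        xk = np.zeros(2)
        KX = np.empty((n, 2))
        for i in range(n):
            xk = Ad @ xk
            P = Ad @ P @ Ad.T + Q
            K = P @ C.T @ np.linalg.inv(C @ P @ C.T + R)
            xk = xk + (K @ (y[i] - C @ xk)).ravel()
            P = (np.eye(2) - K @ C) @ P
            KX[i] = xk
        half = n // 2
        num = np.sqrt(np.mean((trace[half:, :2] - KX[half:]) ** 2))
        den = np.sqrt(np.mean(X[half:] ** 2))
        assert num / den < 0.02


class TestActionStep:
    def test_zero_proprioceptive_error_leaves_action_unchanged(self):
        assert action_step(0.7, dF_da=0.0, dt=0.01) == pytest.approx(0.7)

    def test_sign_convention_drives_eye_toward_prediction(self):
        """Belief predicts faster rightward motion than sensed: the
        precision-weighted velocity error is negative and action must
        increase (accelerating the eye rightward)."""
        params = PursuitParams()
        cfg = StimulusConfig()
        model = pursuit_model(params, cfg)
        settings = FilterSettings()
        ctx = _FilterContext(model, settings)
        mu = np.zeros(ctx.N)
        m_x, m_v = ctx.split(mu)
        m_x[0] = [0.0, 0.5, 0.0, 0.0]  # believed velocity state +0.5
        m_x[1] = [0.5, 0.0, 0.0, 0.0]  # generalized motion of gaze
        s = np.zeros((2, 18))
        s[0, 1:] = model.g(m_x[0])[1:]  # retina consistent
        s[1, 0] = 0.0  # eye actually still
        out = ctx.evaluate(np.concatenate([m_x.ravel(), m_v.ravel()]),
                           s, 0.0)
        new = action_step(0.0, out.dF_da, dt=0.01)
        assert new > 0.0

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            action_step(0.0, 0.0, dt=0.0)


class TestSimulatePursuit:
    def test_identical_seeds_are_bitwise_identical(self, fast_stimulus):
        from pursuitdcm.inference_loop import WorldNoise

        a = simulate_pursuit(fast_stimulus, condition="noisy", seed=5,
                             dt=0.005, noise=WorldNoise())
        b = simulate_pursuit(fast_stimulus, condition="noisy", seed=5,
                             dt=0.005, noise=WorldNoise())
        assert np.array_equal(a.eye, b.eye)
        assert np.array_equal(a.target, b.target)
        assert np.array_equal(a.action, b.action)

    def test_position_error_is_eye_minus_target(self, smooth_sim):
        assert np.array_equal(
            smooth_sim.position_error, smooth_sim.eye - smooth_sim.target)

    def test_tracks_target_through_cycle(self, smooth_sim):
        # tracking with anticipatory excursions around occlusion: the
        # settled-cycle RMS stays well below the path amplitude
        n = int(round(smooth_sim.config.period / smooth_sim.dt))
        rms = np.sqrt(np.mean(smooth_sim.position_error[-n:] ** 2))
        assert rms < 0.5

    def test_static_visible_target_is_a_stable_equilibrium(self):
        """A static visible target with a matching (null-amplitude)
        prior: the closed loop stays at the fixation equilibrium."""
        cfg = StimulusConfig(amplitude=0.0, cycles_per_trial=3,
                             occluder_interval=(0.0, 0.0),
                             phase_offset=0.0)
        params = PursuitParams(theta7=-20.0)
        res = simulate_pursuit(cfg, params, "smooth", dt=0.005)
        # bounded near fixation (the degenerate zero-width occluder
        # leaves a small retinal prediction bias, but no drift)
        assert np.max(np.abs(res.position_error)) < 0.1
        assert abs(res.eye_vel[-1]) < 0.1

    def test_unknown_condition_rejected(self, fast_stimulus):
        with pytest.raises(ValueError):
            simulate_pursuit(fast_stimulus, condition="blurry")


class TestPrecisionPhenotype:
    def test_occluder_increases_steady_lag(self):
        """Removing the occluder sharpens tracking at matched
        parameters."""
        from pursuitdcm.inference_loop import visible_lag

        base = StimulusConfig(cycles_per_trial=3)
        no_occ = StimulusConfig(cycles_per_trial=3,
                                occluder_interval=(0.0, 0.0))
        p = PursuitParams()
        r_occ = simulate_pursuit(base, p, "smooth", dt=0.005)
        r_no = simulate_pursuit(no_occ, p, "smooth", dt=0.005)
        n = int(round(base.period / 0.005))
        rms_occ = np.sqrt(np.mean(r_occ.position_error[-n:] ** 2))
        rms_no = np.sqrt(np.mean(r_no.position_error[-n:] ** 2))
        assert rms_no < rms_occ
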