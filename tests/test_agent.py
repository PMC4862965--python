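"""Subjective pursuit model: flow algebra, weights, predictions."""

import numpy as np
import pytest

from pursuitdcm.agent import (
    PursuitParams,
    attraction_weights,
    flow_jacobian,
    model_flow,
    model_prediction,
    prediction_jacobian,
    prior_cause,
    soft_occluder,
)
from pursuitdcm.stimulus import StimulusConfig


@pytest.fixture
def params():
    return PursuitParams()


class TestAttractionWeights:
    def test_visible_weights(self, params):
        kv, kt = attraction_weights(params, occluded=0)
        assert kv == pytest.approx(params.theta1)
        assert kt == pytest.approx(params.theta3 + params.theta5)

    def test_occluded_weights(self, params):
        kv, kt = attraction_weights(params, occluded=1)
        assert kv == pytest.approx(params.theta1 + params.theta4)
        assert kt == pytest.approx(params.theta3)

    def test_zero_occluder_components_make_weights_constant(self, params):
        p = params.replace(theta4=0.0, theta5=0.0)
        assert attraction_weights(p, 0) == attraction_weights(p, 1)

    def test_occlusion_boosts_hidden_location_suppresses_target(self, params):
        kv0, kt0 = attraction_weights(params, 0)
        kv1, kt1 = attraction_weights(params, 1)
        assert kv1 > kv0 and kt1 < kt0


class TestModelFlow:
    def test_coincident_states_at_rest_are_a_fixed_point(self, params):
        x = np.array([0.3, 0.0, 0.3, 0.0])
        f = model_flow(x, v=0.3, params=params)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_target_attraction_coefficient_is_one_quarter(self, params):
        # x_t' equation: dx_t'/dt = 1/4 (v - x_t) - theta6 x_t'
        x = np.array([0.0, 0.0, 0.2, 0.0])
        f = model_flow(x, v=1.0, params=params)
        assert f[3] == pytest.approx(0.25 * (1.0 - 0.2))

    def test_eye_viscosity_sign(self, params):
        x = np.array([0.0, 1.0, 0.0, 0.0])
        f = model_flow(x, v=0.0, params=params)
        assert f[1] == pytest.approx(-params.theta2 * 1.0)

    def test_gaze_converges_to_target_belief_without_hidden_pull(self, params):
        # kappa_v = 0, static v, strong damping: x_o -> x_t
        p = params.replace(theta1=0.0, theta4=0.0, theta2=3.0)
        x = np.array([-0.8, 0.0, 0.5, 0.0])
        dt = 0.01
        for _ in range(6000):
            # hold the target belief fixed to isolate the eye dynamics
            f = model_flow(x, v=0.5, params=p)
            x = x + dt * np.array([f[0], f[1], 0.0, 0.0])
        assert x[0] == pytest.approx(0.5, abs=0.01)

    def test_jacobian_matches_finite_differences(self, params):
        x0 = np.array([0.31, -0.12, 0.44, 0.05])
        v0 = 0.6
        Jx, Jv = flow_jacobian(x0, v0, params)
        eps = 1e-6
        fd = np.empty((4, 4))
        for j in range(4):
            d = np.zeros(4)
            d[j] = eps
            fd[:, j] = (model_flow(x0 + d, v0, params)
                        - model_flow(x0 - d, v0, params)) / (2 * eps)
        assert np.allclose(Jx, fd, atol=1e-6)
        fdv = (model_flow(x0, v0 + eps, params)
               - model_flow(x0, v0 - eps, params)) / (2 * eps)
        assert np.allclose(Jv, fdv, atol=1e-6)


class TestPriorCause:
    def test_unit_amplitude_at_zero_log_scale(self, params):
        v = prior_cause(0.0, params.replace(theta8=-np.inf))
        assert v == pytest.approx(1.0)

    def test_phase_lead_is_monotone_in_theta8(self, params):
        # larger theta8 -> larger phase argument at t = 0
        t = 0.0
        vals = [prior_cause(t, params.replace(theta8=th))
                for th in (-2.0, -1.0, 0.0)]
        phases = np.arccos(np.clip(vals, -1, 1))
        assert np.all(np.diff(phases) > 0)

    def test_explicit_value(self, params):
        expected = np.exp(params.theta7) * np.cos(np.exp(params.theta8))
        assert prior_cause(0.0, params) == pytest.approx(expected)


class TestModelPrediction:
    def test_believed_occluded_target_predicts_silent_retina(self, params):
        x = np.array([0.0, 0.0, 0.4, 0.0])  # x_t deep in the occluder
        g = model_prediction(x)
        assert np.allclose(g[1:], 0.0, atol=1e-6)

    def test_foveated_visible_belief_peaks_central_channel(self, params):
        x = np.array([-0.5, 0.0, -0.5, 0.0])
        g = model_prediction(x)
        assert g[1 + 8] == pytest.approx(1.0, abs=1e-6)

    def test_proprioceptive_channel_is_gaze(self, params):
        x = np.array([0.123, 0.0, -0.5, 0.0])
        assert model_prediction(x)[0] == pytest.approx(0.123)

    def test_jacobian_matches_finite_differences(self, params):
        x0 = np.array([-0.42, 0.1, -0.35, -0.2])
        J = prediction_jacobian(x0)
        eps = 1e-7
        for j in (0, 2):
            d = np.zeros(4)
            d[j] = eps
            fd = (model_prediction(x0 + d)
                  - model_prediction(x0 - d)) / (2 * eps)
            assert np.allclose(J[:, j], fd, atol=1e-5)


class TestSoftOccluder:
    def test_matches_hard_occluder_away_from_edges(self):
        cfg = StimulusConfig()
        assert soft_occluder(-0.9, cfg) == pytest.approx(1.0, abs=1e-3)
        assert soft_occluder(0.4, cfg) == pytest.approx(0.0, abs=1e-3)
        assert soft_occluder(0.95, cfg) == pytest.approx(1.0, abs=1e-3)

    def test_differentiable_transition(self):
        cfg = StimulusConfig()
        x = np.linspace(-0.05, 0.05, 101)
        vals = soft_occluder(x, cfg)
        assert np.all(np.diff(vals) <= 0)  # entering the occluder


class TestPriorTable:
    def test_roundtrip(self, tmp_path, params):
        path = tmp_path / "priors.json"
        params.save_priors(path)
        loaded = PursuitParams.load_priors(path)
        assert loaded == params

    def test_log_precisions_default_to_table_value(self, params):
        assert params.ln_Pi_s == params.ln_Pi_x == params.ln_Pi_v == 4.0
        assert params.prior_variance == 0.5
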