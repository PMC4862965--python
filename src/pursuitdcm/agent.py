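"""The agent's hierarchical generative model of pursuit.

The agent believes both its centre of gaze x_o and the target x_t are
drawn to a fictive, sinusoidally moving attracting location v (the
hidden cause) that leads the target by a small phase.  The strengths of
attraction of gaze to the attracting location and to the target
(kappa_v, kappa_t) each have a fixed component and an occluder-dependent
component: when the target is behind the occluder the pull of the
hidden location increases and the pull of the target decreases, which is
what lets the model produce anticipatory eye movements.

Time inside the subjective model is normalized to the stimulus period
(one cycle = one time unit), matching the unit-frequency sinusoid of the
hidden cause.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np

from .generalized import GeneralizedVector
from .stimulus import RetinaModel, StimulusConfig

__all__ = [
    "PursuitParams",
    "BeliefState",
    "attraction_weights",
    "model_flow",
    "flow_jacobian",
    "prior_cause",
    "prior_cause_generalized",
    "soft_occluder",
    "model_prediction",
    "prediction_jacobian",
]

#: prior variance of the log-scaling of every estimated parameter
PRIOR_VARIANCE = 0.5
#: prior mean of all three log-precisions
LOG_PRECISION_PRIOR = 4.0


@dataclass
class PursuitParams:
    """Kinetic, precision and prior parameters of the pursuit model.

    theta1/theta4: occluder-independent / -dependent attraction of gaze
    to the hidden attracting location; theta3/theta5: the same for the
    target; theta2/theta6: viscosity of eye and target motion;
    theta7/theta8: log amplitude and log phase-lead of the attracting
    location.  ln_Pi_*: log-precisions of fluctuations at the sensory,
    hidden-state and hidden-cause levels.
    """

    theta1: float = 0.25
    theta2: float = 0.5
    theta3: float = 0.5
    theta4: float = 1.5
    theta5: float = 1.5
    theta6: float = 0.25
    theta7: float = 0.0
    theta8: float = float(np.log(2.0 * np.pi / 12.0))
    ln_Pi_s: float = LOG_PRECISION_PRIOR
    ln_Pi_x: float = LOG_PRECISION_PRIOR
    ln_Pi_v: float = LOG_PRECISION_PRIOR
    prior_variance: float = PRIOR_VARIANCE
    #: sigmoid edge width of the subjective occluder (normalized units)
    occluder_softness: float = 0.02

    PARAM_NAMES = (
        "theta1", "theta2", "theta3", "theta4", "theta5", "theta6",
        "theta7", "theta8", "ln_Pi_s", "ln_Pi_x", "ln_Pi_v",
    )

    def __post_init__(self) -> None:
        if self.prior_variance <= 0:
            raise ValueError("prior variance must be positive")

    def replace(self, **kwargs) -> "PursuitParams":
        d = self.to_dict()
        d.update(kwargs)
        return PursuitParams(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def prior_table(self) -> list[dict]:
        """Flat prior table: {name, prior_mean, prior_variance, scale}."""
        log_scale = {"theta7", "theta8", "ln_Pi_s", "ln_Pi_x", "ln_Pi_v"}
        return [
            {
                "name": name,
                "prior_mean": getattr(self, name),
                "prior_variance": self.prior_variance,
                "scale": "log" if name in log_scale else "linear",
            }
            for name in self.PARAM_NAMES
        ]

    def save_priors(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.prior_table(), fh, indent=1)

    @classmethod
    def load_priors(cls, path) -> "PursuitParams":
        with open(path) as fh:
            table = json.load(fh)
        return cls(**{row["name"]: row["prior_mean"] for row in table})


@dataclass
class BeliefState:
    """Posterior expectations over hidden states and the cause.

    mu_x holds (x_o, x_o', x_t, x_t') in generalized coordinates;
    mu_v holds the attracting location v.
    """

    mu_x: GeneralizedVector
    mu_v: GeneralizedVector

    @classmethod
    def zeros(cls, order_x: int = 4, order_v: int = 2) -> "BeliefState":
        return cls(
            GeneralizedVector(np.zeros((4, order_x))),
            GeneralizedVector(np.zeros((1, order_v))),
        )


def attraction_weights(
    params: PursuitParams, occluded: float
) -> tuple[float, float]:
    """Attraction weights (kappa_v, kappa_t) given occlusion state.

    ``occluded`` may be fractional (sigmoid-softened occluder edge).
    Occlusion boosts attraction to the hidden location and suppresses
    attraction to the target.
    """
    kappa_v = params.theta1 + occluded * params.theta4
    kappa_t = params.theta3 + (1.0 - occluded) * params.theta5
    return kappa_v, kappa_t


def _occlusion_of(x_t: float, params: PursuitParams,
                  config: StimulusConfig) -> float:
    return 1.0 - soft_occluder(x_t, config, params.occluder_softness)


def model_flow(
    x: np.ndarray,
    v: float,
    params: PursuitParams,
    config: StimulusConfig | None = None,
) -> np.ndarray:
    """Equations of motion the agent believes govern (x_o, x_o', x_t, x_t').

    dx_o  = x_o'
    dx_o' = kappa_v (v - x_o) + kappa_t (x_t - x_o) - theta2 x_o'
    dx_t  = x_t'
    dx_t' = 1/4 (v - x_t) - theta6 x_t'
    """
    if config is None:
        config = StimulusConfig()
    x_o, x_o_dot, x_t, x_t_dot = x
    occ = _occlusion_of(x_t, params, config)
    kappa_v, kappa_t = attraction_weights(params, occ)
    return np.array(
        [
            x_o_dot,
            kappa_v * (v - x_o) + kappa_t * (x_t - x_o)
            - params.theta2 * x_o_dot,
            x_t_dot,
            0.25 * (v - x_t) - params.theta6 * x_t_dot,
        ]
    )


def flow_jacobian(
    x: np.ndarray,
    v: float,
    params: PursuitParams,
    config: StimulusConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobians (df/dx, df/dv) of :func:`model_flow`.

    The occlusion state entering the attraction weights is treated as
    locally constant (its sigmoid derivative contributes only within the
    narrow occluder edges and is omitted from the linearisation).
    """
    if config is None:
        config = StimulusConfig()
    occ = _occlusion_of(x[2], params, config)
    kappa_v, kappa_t = attraction_weights(params, occ)
    dfdx = np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [-(kappa_v + kappa_t), -params.theta2, kappa_t, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, -0.25, -params.theta6],
        ]
    )
    dfdv = np.array([0.0, kappa_v, 0.0, 0.25])
    return dfdx, dfdv


def prior_cause(
    t: float | np.ndarray,
    params: PursuitParams,
    omega_v: float = 0.0,
    phase_offset: float = 0.0,
) -> float | np.ndarray:
    """Prior expectation of the attracting location at normalized time t.

    v = exp(theta7) * cos(2 pi t + exp(theta8)) + omega_v: a unit-period
    sinusoid whose amplitude and phase lead are log-parameterised.
    ``phase_offset`` carries the stimulus start convention (pi when the
    trial starts at the left of the path), which the agent knows.
    """
    return (
        np.exp(params.theta7)
        * np.cos(
            2.0 * np.pi * np.asarray(t, dtype=float)
            + phase_offset
            + np.exp(params.theta8)
        )
        + omega_v
    )


def prior_cause_generalized(
    t: float, params: PursuitParams, order: int = 2,
    phase_offset: float = 0.0,
) -> np.ndarray:
    """Prior cause and its first ``order - 1`` time derivatives."""
    amp = np.exp(params.theta7)
    phase = 2.0 * np.pi * t + phase_offset + np.exp(params.theta8)
    out = np.empty(order)
    for k in range(order):
        out[k] = amp * (2.0 * np.pi) ** k * np.cos(phase + k * np.pi / 2.0)
    return out


def soft_occluder(
    x: float | np.ndarray,
    config: StimulusConfig | None = None,
    softness: float = 0.02,
) -> float | np.ndarray:
    """Differentiable occluder: ~1 when visible, ~0 when occluded.

    Product of two logistic edges replaces the hard indicator so that
    gradients through the subjective occluder are defined.
    """
    if config is None:
        config = StimulusConfig()
    lo, hi = config.occluder_interval
    x = np.asarray(x, dtype=float)
    inside = _sigmoid((x - lo) / softness) * _sigmoid((hi - x) / softness)
    return 1.0 - inside


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _soft_occluder_grad(x: float, config: StimulusConfig, softness: float) -> float:
    lo, hi = config.occluder_interval
    a = _sigmoid((x - lo) / softness)
    b = _sigmoid((hi - x) / softness)
    da = a * (1 - a) / softness
    db = -b * (1 - b) / softness
    return -(da * b + a * db)


def model_prediction(
    x: np.ndarray,
    retina: RetinaModel | None = None,
    config: StimulusConfig | None = None,
    softness: float = 0.02,
) -> np.ndarray:
    """Predicted sensations given believed states (x_o, ., x_t, .).

    Returns an 18-vector: the proprioceptive prediction x_o followed by
    17 retinal channel predictions built from the *believed* target
    position x_t and the subjective (softened) occluder O(x_t).
    """
    if retina is None:
        retina = RetinaModel()
    if config is None:
        config = StimulusConfig()
    x_o, _, x_t, _ = x
    o = soft_occluder(x_t, config, softness)
    d = retina.centers + x_o - x_t
    g = np.empty(18)
    g[0] = x_o
    g[1:] = o * np.exp(-(d**2) / retina.width**2)
    return g


def prediction_jacobian(
    x: np.ndarray,
    retina: RetinaModel | None = None,
    config: StimulusConfig | None = None,
    softness: float = 0.02,
) -> np.ndarray:
    """Analytic 18 x 4 Jacobian of :func:`model_prediction` w.r.t. x."""
    if retina is None:
        retina = RetinaModel()
    if config is None:
        config = StimulusConfig()
    x_o, _, x_t, _ = x
    o = soft_occluder(x_t, config, softness)
    do = _soft_occluder_grad(x_t, config, softness)
    d = retina.centers + x_o - x_t
    e = np.exp(-(d**2) / retina.width**2)
    de = -2.0 * d / retina.width**2 * e
    J = np.zeros((18, 4))
    J[0, 0] = 1.0
    J[1:, 0] = o * de
    J[1:, 2] = -o * de + do * e
    return J
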