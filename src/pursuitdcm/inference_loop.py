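"""Closed-loop perception and action by free-energy minimisation.

Beliefs live in generalized coordinates and follow a gradient flow on
variational free energy, mu_dot = D mu - dF/dmu, while action descends
the same free energy through the proprioceptive prediction error only.
Integrating perception and the oculomotor plant in lock-step yields
simulated eye trajectories and position errors.

The filter core is generic over the (f, g) model functions, so the same
machinery drives the pursuit simulation and the linear-Gaussian
reductions that are cross-checked against classical Kalman filtering.

Time units: the kinetic equations of the pursuit model are written per
*characteristic time unit* of the oculomotor system; one stimulus cycle
spans ``UNITS_PER_CYCLE`` = 32 such units (so, with the 3.94 s period,
one unit is ~123 ms).  The public API uses seconds; the conversion is
internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .agent import (
    BeliefState,
    PursuitParams,
    flow_jacobian,
    model_flow,
    model_prediction,
    prediction_jacobian,
)
from .generalized import SmoothnessModel, shift_operator
from .stimulus import (
    RetinaModel,
    StimulusConfig,
    occluder_value,
    phase_noise_series,
)

__all__ = [
    "UNITS_PER_CYCLE",
    "FilterSettings",
    "GenerativeModel",
    "FreeEnergyGradients",
    "ActionState",
    "WorldNoise",
    "SimulationResult",
    "NumericalInstabilityError",
    "pursuit_model",
    "free_energy",
    "perception_step",
    "action_step",
    "run_filter",
    "simulate_pursuit",
    "visible_lag",
    "occlusion_anticipation",
]

#: characteristic time units per stimulus cycle; the 2*pi/32 phase-lead
#: prior of the attracting location equals one such unit
UNITS_PER_CYCLE = 32.0


class NumericalInstabilityError(RuntimeError):
    """Raised when the belief flow diverges; names the failing step."""


@dataclass
class FilterSettings:
    """Embedding orders, smoothness and step sizes of the filter.

    Orders default to 4 for hidden states and 2 for causes and sensory
    data.  ``smoothness`` (in model time units) is the assumed Gaussian
    autocorrelation scale of analytic fluctuations.  ``lr_mu``/``lr_a``
    scale the belief and action gradient flows; defaults keep the
    smooth-condition pursuit simulation stable at 1 ms resolution.
    """

    order_x: int = 4
    order_v: int = 2
    order_s: int = 2
    smoothness: float = 0.5
    lr_mu: float = 1.0
    lr_a: float = 8.0
    divergence_norm: float = 1e6


@dataclass
class GenerativeModel:
    """A hierarchical model presented to the generalized filter.

    f/g are the flow of hidden states and the observation function;
    fx, fv, gx their Jacobians; eta(t, order) the generalized prior over
    causes.  Log-precisions weight sensory, state-motion and cause
    prediction errors; ``obs_weights`` optionally rescales the precision
    per (sensory order, channel) — e.g. to balance a many-channel
    modality against a single proprioceptive channel.
    """

    n_states: int
    n_causes: int
    n_obs: int
    f: Callable
    fx: Callable
    fv: Callable
    g: Callable
    gx: Callable
    eta: Callable
    ln_pi_s: float = 4.0
    ln_pi_x: float = 4.0
    ln_pi_v: float = 4.0
    obs_weights: np.ndarray | None = None
    #: optional fused evaluator (x0, v0, t) -> (f0, Fx, Fv, g0, G)
    fused: Callable | None = None


@dataclass
class FreeEnergyGradients:
    """Free energy with its belief-space gradient and curvature."""

    F: float
    grad: np.ndarray
    hessian: np.ndarray
    dF_da: float
    eps_s: np.ndarray
    eps_x: np.ndarray
    eps_v: np.ndarray


@dataclass
class ActionState:
    """Oculomotor drive with its history."""

    a: float = 0.0
    history: list = field(default_factory=list)


class _FilterContext:
    """Precomputed precision/derivative matrices for one model."""

    def __init__(self, model: GenerativeModel, settings: FilterSettings):
        self.model = model
        self.settings = settings
        nx, nv, ns = settings.order_x, settings.order_v, settings.order_s
        dx, dv, do = model.n_states, model.n_causes, model.n_obs
        self.nx, self.nv, self.ns = nx, nv, ns
        self.dx, self.dv, self.do = dx, dv, do
        self.N = dx * nx + dv * nv

        s_x = SmoothnessModel(settings.smoothness, nx)
        s_v = SmoothnessModel(settings.smoothness, nv)
        s_s = SmoothnessModel(settings.smoothness, ns)
        P_s = np.exp(model.ln_pi_s) * np.kron(
            np.linalg.inv(s_s.covariance()), np.eye(do)
        )
        if model.obs_weights is not None:
            w = np.sqrt(np.asarray(model.obs_weights, float).ravel())
            P_s = P_s * np.outer(w, w)
        self.P_s = P_s
        self.P_x = np.exp(model.ln_pi_x) * np.kron(
            np.linalg.inv(s_x.covariance()), np.eye(dx)
        )
        self.P_v = np.exp(model.ln_pi_v) * np.kron(
            np.linalg.inv(s_v.covariance()), np.eye(dv)
        )
        self.D = np.zeros((self.N, self.N))
        self.D[: dx * nx, : dx * nx] = np.kron(shift_operator(nx), np.eye(dx))
        self.D[dx * nx :, dx * nx :] = np.kron(shift_operator(nv), np.eye(dv))
        self.E_s = np.eye(ns, nx)
        self.E_v = np.eye(nx, nv)
        self._I = np.eye(self.N)
        # preallocated error-Jacobian buffers (block-sparse structure)
        self._A_s = np.zeros((ns * do, self.N))
        self._A_x = np.zeros((nx * dx, self.N))
        self._A_v = np.zeros((nv * dv, self.N))
        self._A_v[:, dx * nx:] = np.eye(nv * dv)
        self._f_tilde = np.empty((nx, dx))
        self._g_tilde = np.empty((ns, do))

    def split(self, mu: np.ndarray):
        dx, nx = self.dx, self.nx
        m_x = mu[: dx * nx].reshape(nx, dx)
        m_v = mu[dx * nx :].reshape(self.nv, self.dv)
        return m_x, m_v

    def evaluate(self, mu: np.ndarray, s_tilde: np.ndarray,
                 t: float) -> FreeEnergyGradients:
        m = self.model
        nx, nv, ns = self.nx, self.nv, self.ns
        dx, dv, do = self.dx, self.dv, self.do
        m_x, m_v = self.split(mu)
        x0, v0 = m_x[0], m_v[0]

        if m.fused is not None:
            f0, Fx, Fv, g0, G = m.fused(x0, v0, t)
            Fv = Fv.reshape(dx, dv)
        else:
            Fx = m.fx(x0, v0, t)
            Fv = np.atleast_2d(m.fv(x0, v0, t)).reshape(dx, dv)
            G = np.atleast_2d(m.gx(x0)).reshape(do, dx)
            f0 = m.f(x0, v0, t)
            g0 = m.g(x0)

        f_tilde = self._f_tilde
        f_tilde[0] = f0
        f_tilde[1:] = m_x[1:] @ Fx.T
        for k in range(1, min(nv, nx)):
            f_tilde[k] += Fv @ m_v[k]
        g_tilde = self._g_tilde
        g_tilde[0] = g0
        g_tilde[1:] = m_x[1:ns] @ G.T

        eps_x = np.empty((nx, dx))
        eps_x[:-1] = m_x[1:]
        eps_x[-1] = 0.0
        eps_x -= f_tilde
        eps_x = eps_x.ravel()
        eps_s = (s_tilde[:ns].reshape(ns, do) - g_tilde).ravel()
        eta = m.eta(t, nv).reshape(nv, dv)
        eps_v = (m_v - eta).ravel()

        ws = self.P_s @ eps_s
        wx = self.P_x @ eps_x
        wv = self.P_v @ eps_v
        F_val = 0.5 * (eps_s @ ws + eps_x @ wx + eps_v @ wv)

        nX = dx * nx
        A_s, A_x, A_v = self._A_s, self._A_x, self._A_v
        for k in range(ns):
            A_s[k * do:(k + 1) * do, k * dx:(k + 1) * dx] = -G
        A_x[:, :nX] = self.D[:nX, :nX]
        for k in range(nx):
            A_x[k * dx:(k + 1) * dx, k * dx:(k + 1) * dx] -= Fx
        for k in range(nv):
            A_x[k * dx:(k + 1) * dx, nX + k * dv:nX + (k + 1) * dv] = -Fv

        grad = A_s.T @ ws + A_x.T @ wx + A_v.T @ wv
        hess = (
            A_s.T @ self.P_s @ A_s
            + A_x.T @ self.P_x @ A_x
            + A_v.T @ self.P_v @ A_v
        )
        # action sees only the order-1 proprioceptive error (channel 0)
        dF_da = float(ws[do]) if ns > 1 else 0.0
        return FreeEnergyGradients(F_val, grad, hess, dF_da,
                                   eps_s, eps_x, eps_v)


def free_energy(
    beliefs: np.ndarray | BeliefState,
    sensation: np.ndarray,
    model: GenerativeModel,
    settings: FilterSettings | None = None,
    t: float = 0.0,
) -> FreeEnergyGradients:
    """Precision-weighted squared prediction error and its gradients.

    ``sensation`` is a generalized sensory sample (order_s x n_obs).
    Returns free energy with gradient and Gauss-Newton curvature w.r.t.
    the flattened beliefs, plus the action gradient through the
    proprioceptive channel.
    """
    settings = settings or FilterSettings()
    mu = _as_flat(beliefs, settings)
    if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(sensation)):
        raise ValueError("non-finite beliefs or sensations")
    return _FilterContext(model, settings).evaluate(
        mu, np.asarray(sensation, dtype=float), t
    )


def _as_flat(beliefs, settings: FilterSettings) -> np.ndarray:
    if isinstance(beliefs, BeliefState):
        return np.concatenate(
            [beliefs.mu_x.values.T.ravel(), beliefs.mu_v.values.T.ravel()]
        )
    return np.asarray(beliefs, dtype=float).ravel()


def perception_step(
    mu: np.ndarray,
    gradients: FreeEnergyGradients,
    dt: float,
    ctx: _FilterContext,
) -> np.ndarray:
    """One update of the belief gradient flow mu_dot = D mu - dF/dmu.

    The stiff, precision-weighted flow is integrated by a backward-Euler
    step on its local (Gauss-Newton) linearisation; for small dt this
    reduces to an explicit Euler step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lr = ctx.settings.lr_mu
    mu_dot = ctx.D @ mu - lr * gradients.grad
    J = ctx.D - lr * gradients.hessian
    delta = np.linalg.solve(ctx._I - dt * J, dt * mu_dot)
    out = mu + delta
    norm = float(np.linalg.norm(out))
    if not np.isfinite(norm) or norm > ctx.settings.divergence_norm:
        raise NumericalInstabilityError(
            f"belief flow diverged (|mu| = {norm:.3g})"
        )
    return out


def action_step(
    action: float, dF_da: float, dt: float, lr_a: float = 8.0
) -> float:
    """Gradient descent of free energy with respect to action.

    Action can only change the proprioceptive prediction error, so its
    gradient is the precision-weighted order-1 proprioceptive error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = action - dt * lr_a * dF_da
    if not np.isfinite(a):
        raise ValueError("action became non-finite")
    return a


def pursuit_model(
    params: PursuitParams,
    config: StimulusConfig,
    retina: RetinaModel | None = None,
) -> GenerativeModel:
    """Package the subjective pursuit model for the generalized filter.

    Sensory precision is balanced per modality: the single
    proprioceptive channel carries the same total weight as the 17
    retinal channels together; retinal data enter at order 0 only
    (velocity information reaches the filter proprioceptively).
    """
    retina = retina or RetinaModel()
    soft = params.occluder_softness
    omega = 2.0 * np.pi / UNITS_PER_CYCLE
    amp = np.exp(params.theta7)
    lead = np.exp(params.theta8)
    phi0 = config.phase_offset

    def eta(t, order):
        ph = omega * t + phi0 + lead
        return np.array(
            [amp * omega**k * np.cos(ph + k * np.pi / 2.0)
             for k in range(order)]
        )

    w = np.zeros((2, 18))
    w[0, 0] = w[1, 0] = 1.0
    w[0, 1:] = 1.0 / 17.0

    centers = retina.centers
    inv_w2 = 1.0 / retina.width**2
    lo, hi = config.occluder_interval
    th1, th2, th3 = params.theta1, params.theta2, params.theta3
    th4, th5, th6 = params.theta4, params.theta5, params.theta6

    def fused(x, v, t):
        x_o, x_o_dot, x_t, x_t_dot = x
        vv = float(v[0])
        # subjective occluder (sigmoid edges) and its gradient
        za = 0.5 * (1.0 + np.tanh(0.5 * (x_t - lo) / soft))
        zb = 0.5 * (1.0 + np.tanh(0.5 * (hi - x_t) / soft))
        occ = za * zb              # occlusion degree in [0, 1]
        o = 1.0 - occ              # visibility of the believed target
        do_dxt = -(za * (1 - za) * zb - zb * (1 - zb) * za) / soft
        kappa_v = th1 + occ * th4
        kappa_t = th3 + (1.0 - occ) * th5
        f0 = np.array([
            x_o_dot,
            kappa_v * (vv - x_o) + kappa_t * (x_t - x_o) - th2 * x_o_dot,
            x_t_dot,
            0.25 * (vv - x_t) - th6 * x_t_dot,
        ])
        Fx = np.array([
            [0.0, 1.0, 0.0, 0.0],
            [-(kappa_v + kappa_t), -th2, kappa_t, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [0.0, 0.0, -0.25, -th6],
        ])
        Fv = np.array([0.0, kappa_v, 0.0, 0.25])
        d = centers + x_o - x_t
        e = np.exp(-(d * d) * inv_w2)
        de = -2.0 * d * inv_w2 * e
        g0 = np.empty(18)
        g0[0] = x_o
        g0[1:] = o * e
        G = np.zeros((18, 4))
        G[0, 0] = 1.0
        G[1:, 0] = o * de
        G[1:, 2] = -o * de + do_dxt * e
        return f0, Fx, Fv, g0, G

    return GenerativeModel(
        n_states=4,
        n_causes=1,
        n_obs=18,
        f=lambda x, v, t: model_flow(x, float(v[0]), params, config),
        fx=lambda x, v, t: flow_jacobian(x, float(v[0]), params, config)[0],
        fv=lambda x, v, t: flow_jacobian(x, float(v[0]), params, config)[1],
        g=lambda x: model_prediction(x, retina, config, soft),
        gx=lambda x: prediction_jacobian(x, retina, config, soft),
        eta=eta,
        ln_pi_s=params.ln_Pi_s,
        ln_pi_x=params.ln_Pi_x,
        ln_pi_v=params.ln_Pi_v,
        obs_weights=w,
        fused=fused,
    )


@dataclass
class WorldNoise:
    """Random fluctuations of the generative process (per trial).

    sigma_s: SD of OU-smoothed sensory noise on the proprioceptive
    channel (normalized position units); sigma_x: intensity of white
    accelerative noise on the plant (per sqrt model-time-unit); tau_s:
    correlation time of the sensory noise in model time units.
    """

    sigma_s: float = 0.02
    sigma_x: float = 0.1
    tau_s: float = 0.2


@dataclass
class SimulationResult:
    """Output of one closed-loop pursuit simulation.

    ``position_error`` is eye minus target pointwise, the behavioural
    data feature used by the meta-Bayesian inversion.
    """

    time: np.ndarray
    target: np.ndarray
    target_expected: np.ndarray
    eye: np.ndarray
    eye_vel: np.ndarray
    visible: np.ndarray
    action: np.ndarray
    #: eye minus instantaneous target, pointwise
    position_error: np.ndarray
    #: eye minus the expected (noise-free) target path — the behavioural
    #: data feature for inversion: in the Noisy condition the
    #: phase-walk makes the instantaneous target essentially white, and
    #: the model's position error is defined against the underlying
    #: sinusoidal cause
    position_error_expected: np.ndarray
    beliefs: np.ndarray | None
    free_energy: np.ndarray
    config: StimulusConfig
    params: PursuitParams
    condition: str
    seed: int | None
    dt: float


def simulate_pursuit(
    stimulus: StimulusConfig | None = None,
    params: PursuitParams | None = None,
    condition: str = "smooth",
    seed: int | None = None,
    dt: float | None = None,
    noise: WorldNoise | None = None,
    settings: FilterSettings | None = None,
    retina: RetinaModel | None = None,
    record_beliefs: bool = False,
) -> SimulationResult:
    """Run world and agent in lock-step for one trial.

    ``noise=None`` gives the deterministic (expected) trajectory used by
    the behavioural inversion; a :class:`WorldNoise` adds trial-to-trial
    fluctuations.  Bitwise deterministic given the seed.
    """
    stimulus = stimulus or StimulusConfig()
    params = params or PursuitParams()
    settings = settings or FilterSettings()
    retina = retina or RetinaModel()
    if condition not in ("smooth", "noisy"):
        raise ValueError(f"unknown condition {condition!r}")
    dt = stimulus.dt if dt is None else dt
    tau_u = stimulus.period / UNITS_PER_CYCLE
    h = dt / tau_u
    omega = 2.0 * np.pi / UNITS_PER_CYCLE
    n_steps = int(round(stimulus.cycles_per_trial * stimulus.period / dt))
    # independent streams: the stimulus (phase-noise) realization is
    # reproducible from the seed alone, regardless of whether world
    # noise is enabled — the experimenter knows the stimulus shown on
    # each trial, so model predictions can condition on it
    ss = np.random.SeedSequence(seed)
    phase_seed, world_seed = ss.spawn(2)
    rng = np.random.default_rng(world_seed)

    model = pursuit_model(params, stimulus, retina)
    ctx = _FilterContext(model, settings)

    if condition == "noisy" and stimulus.noise_variance > 0:
        cfg_dt = stimulus if dt == stimulus.dt else replace(stimulus, dt=dt)
        walk = phase_noise_series(n_steps, cfg_dt,
                                  np.random.default_rng(phase_seed))
    else:
        walk = np.zeros(n_steps)

    amp, phi0 = stimulus.amplitude, stimulus.phase_offset
    x_o = amp * np.cos(phi0)  # eye starts on the stationary target
    x_o_dot = 0.0  # velocity per model time unit
    a = 0.0
    mu = np.zeros(ctx.N)
    m_x, m_v = ctx.split(mu)
    m_x[0] = [x_o, 0.0, x_o, 0.0]
    m_v[:, 0] = model.eta(0.0, ctx.nv)

    if noise is not None:
        w_s = 0.0
        alpha = float(np.exp(-h / max(noise.tau_s, 1e-9)))
        s_scale = noise.sigma_s * np.sqrt(1.0 - alpha**2)

    out = {k: np.empty(n_steps)
           for k in ("target", "target_exp", "eye", "eye_vel", "visible",
                     "action", "F")}
    bel = np.empty((n_steps, ctx.N)) if record_beliefs else None
    inv_w2 = 1.0 / retina.width**2
    s_tilde = np.zeros((ctx.ns, ctx.do))

    for i in range(n_steps):
        u = i * h
        v = amp * np.cos(omega * u + phi0 + walk[i])
        v_dot = -amp * omega * np.sin(omega * u + phi0)
        vis = occluder_value(v, stimulus)

        prop = x_o
        if noise is not None:
            w_s = alpha * w_s + s_scale * rng.standard_normal()
            prop = x_o + w_s
        s_tilde[0, 0] = prop
        dcent = retina.centers + x_o - v
        s_tilde[0, 1:] = vis * np.exp(-(dcent**2) * inv_w2)
        s_tilde[1, 0] = x_o_dot

        try:
            grads = ctx.evaluate(mu, s_tilde, u)
            mu = perception_step(mu, grads, h, ctx)
        except NumericalInstabilityError as err:
            raise NumericalInstabilityError(
                f"{err} at step {i} (t = {i * dt:.3f} s)"
            ) from None
        a = action_step(a, grads.dF_da, h, settings.lr_a)

        omega_x = 0.0
        if noise is not None:
            omega_x = noise.sigma_x * rng.standard_normal() / np.sqrt(h)
        x_o = x_o + h * x_o_dot
        x_o_dot = x_o_dot + h * (a - x_o_dot + omega_x)

        out["target"][i] = v
        out["target_exp"][i] = amp * np.cos(omega * u + phi0)
        out["eye"][i] = x_o
        out["eye_vel"][i] = x_o_dot
        out["visible"][i] = vis
        out["action"][i] = a
        out["F"][i] = grads.F
        if record_beliefs:
            bel[i] = mu

    time = np.arange(n_steps) * dt
    return SimulationResult(
        time=time,
        target=out["target"],
        target_expected=out["target_exp"],
        eye=out["eye"],
        eye_vel=out["eye_vel"] / tau_u,  # per second
        visible=out["visible"],
        action=out["action"],
        position_error=out["eye"] - out["target"],
        position_error_expected=out["eye"] - out["target_exp"],
        beliefs=bel,
        free_energy=out["F"],
        config=stimulus,
        params=params,
        condition=condition,
        seed=seed,
        dt=dt,
    )


def run_filter(
    model: GenerativeModel,
    observations: np.ndarray,
    dt: float,
    settings: FilterSettings | None = None,
    mu0: np.ndarray | None = None,
) -> np.ndarray:
    """Offline generalized filtering of a sampled observation sequence.

    ``observations`` has shape (n_steps, order_s, n_obs) — generalized
    sensory samples — or (n_steps, n_obs), in which case higher sensory
    orders are filled by finite differences.  Returns the posterior
    expectation trajectory (n_steps, N).  No action is emitted.
    """
    settings = settings or FilterSettings()
    ctx = _FilterContext(model, settings)
    obs = np.asarray(observations, dtype=float)
    if obs.ndim == 2:
        full = np.zeros((obs.shape[0], settings.order_s, obs.shape[1]))
        full[:, 0] = obs
        if settings.order_s > 1:
            full[1:, 1] = np.diff(obs, axis=0) / dt
            full[0, 1] = full[1, 1]
        obs = full
    mu = np.zeros(ctx.N) if mu0 is None else np.asarray(mu0, dtype=float)
    trace = np.empty((obs.shape[0], ctx.N))
    for i in range(obs.shape[0]):
        grads = ctx.evaluate(mu, obs[i], i * dt)
        mu = perception_step(mu, grads, dt, ctx)
        trace[i] = mu
    return trace


# ---------------------------------------------------------------------------
# trajectory summaries used to characterise precision effects


def _settled(result: SimulationResult, settle_cycles: int = 2) -> np.ndarray:
    n_per = int(round(result.config.period / result.dt))
    sel = np.zeros(len(result.time), dtype=bool)
    sel[min(settle_cycles * n_per, len(sel) - n_per):] = True
    return sel


def _direction(result: SimulationResult) -> np.ndarray:
    cfg = result.config
    u = result.time / cfg.period
    return np.sign(-np.sin(2 * np.pi * u + cfg.phase_offset))


def visible_lag(result: SimulationResult, settle_cycles: int = 2) -> float:
    """Phase lag (radians) of the eye behind the target.

    The eye trace over the settled cycles is projected on the stimulus
    fundamental; positive values mean the eye peaks after the target
    (lag), negative values that it leads (anticipation dominating).
    """
    cfg = result.config
    sel = _settled(result, settle_cycles)
    ph = 2 * np.pi * result.time / cfg.period + cfg.phase_offset
    basis = np.c_[np.cos(ph[sel]), np.sin(ph[sel])]
    coef, *_ = np.linalg.lstsq(basis, result.eye[sel], rcond=None)
    return float(np.arctan2(coef[1], coef[0]))


def occlusion_anticipation(result: SimulationResult,
                           settle_cycles: int = 2) -> float:
    """Mean peak anticipatory displacement during occlusion episodes.

    For each settled occlusion episode, the largest excursion of the eye
    ahead of the target along its direction of motion; averaged over
    episodes.
    """
    sel = _settled(result, settle_cycles) & (result.visible == 0)
    ahead = (result.eye - result.target) * _direction(result)
    idx = np.where(sel)[0]
    if idx.size == 0:
        raise ValueError("no occluded samples after the settling period")
    groups = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    peaks = [float(np.max(ahead[g])) for g in groups if len(g) > 3]
    return float(np.mean(peaks))
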