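"""Meta-Bayesian inversion of pursuit behaviour.

The observed data feature is the position error a(t) = x_o - v (eye
minus target), cycle-averaged and normalized.  A generative model of
this feature is the deterministic active-inference simulation itself:
p(a | eta, theta_o) = N(a*, Sigma(theta_o)) with a* the Bayes-optimal
position error produced by a subject with parameters eta.  Inverting
this observation model with variational Laplace yields posteriors over
the subject's kinetic parameters and (log-)precisions — i.e. it
estimates the priors the subject itself used.

Condition effects (Smooth vs Noisy target motion) are estimated as
additive deltas on selected parameters, shared parameters being fitted
jointly to both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agent import PursuitParams
from .inference_loop import FilterSettings, simulate_pursuit
from .laplace import PosteriorDensity, bayesian_model_average, variational_laplace
from .stimulus import StimulusConfig

__all__ = [
    "ObservationModel",
    "ConditionEffectModel",
    "FitConfig",
    "PrecisionSurface",
    "precision_surface",
    "predict_position_error",
    "fit_pursuit",
    "fit_precision",
    "fit_conditions",
    "bayesian_model_average",
    "default_effect_models",
]

#: parameters estimated on a log-scaling / additive scale with the
#: shared prior variance of one half
_ALL_PARAMS = PursuitParams.PARAM_NAMES


@dataclass
class ObservationModel:
    """Gaussian observation noise on the position-error series.

    i.i.d. by default; ``ar1`` prewhitens data and prediction with the
    given first-order autocorrelation before fitting.
    """

    ar1: float = 0.0

    def whiten(self, series: np.ndarray) -> np.ndarray:
        if self.ar1 == 0.0:
            return series
        out = series.copy()
        out[1:] = series[1:] - self.ar1 * series[:-1]
        return out


@dataclass
class ConditionEffectModel:
    """Which parameters acquire a condition (target-noise) delta."""

    effects: tuple[str, ...] = ("ln_Pi_s",)

    def __post_init__(self) -> None:
        unknown = set(self.effects) - set(_ALL_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")


@dataclass
class FitConfig:
    """Resolution of the forward simulations used during inversion.

    The trajectory is simulated for ``cycles`` cycles and the last cycle
    (past the settling transient) is reported on ``n_points`` samples.
    Defaults trade integration accuracy for speed; the same config must
    be used to produce data and predictions so that discretisation
    effects cancel.
    """

    dt: float = 0.005
    cycles: int = 2
    n_points: int = 64
    max_iter: int = 12
    tol: float = 0.02
    fd_step: float = 0.05
    fd_mode: str = "forward"
    #: starting offsets for the first free parameter; the best-fitting
    #: one seeds the Gauss-Newton ascent — dense, because the
    #: waveform's mean-square distance to the data is multimodal in
    #: the ln Pi_s offset
    init_offsets: tuple = (-1.2, -0.8, -0.4, 0.0, 0.4, 0.8, 1.2, 1.6,
                           2.0, 2.4)


def fold_cycles(series: np.ndarray, config: StimulusConfig, dt: float,
                n_points: int) -> np.ndarray:
    """Average a trial's trace over its stimulus cycles.

    All cycles are used (the settling transient of the first cycle is
    part of the shared protocol, so it cancels between data and
    prediction) and the mean cycle is resampled to ``n_points``.
    """
    m = int(round(config.period / dt))
    n_cyc = len(series) // m
    folded = series[: n_cyc * m].reshape(n_cyc, m).mean(axis=0)
    grid = np.linspace(0.0, m - 1, n_points)
    return np.interp(grid, np.arange(m), folded)




def predict_position_error(
    params: PursuitParams,
    stimulus: StimulusConfig | None = None,
    condition: str = "smooth",
    fit: FitConfig | None = None,
    settings: FilterSettings | None = None,
) -> np.ndarray:
    """Bayes-optimal position error a*(t) over one (settled) cycle.

    Runs the deterministic (noise-free expectation) simulation — for the
    Noisy condition the expected target path is the underlying smooth
    sinusoid, the condition acting only through the parameters — and
    returns the cycle-averaged eye-minus-target on the fitting grid.
    Invariant to observation-noise parameters by construction.
    """
    fit = fit or FitConfig()
    stimulus = stimulus or StimulusConfig()
    if stimulus.cycles_per_trial != fit.cycles:
        from dataclasses import replace

        stimulus = replace(stimulus, cycles_per_trial=fit.cycles)
    res = simulate_pursuit(
        stimulus, params, "smooth", seed=None, dt=fit.dt, noise=None,
        settings=settings,
    )
    return fold_cycles(res.position_error_expected, stimulus, fit.dt,
                       fit.n_points)


def _apply(params: PursuitParams, names: tuple[str, ...],
           values: np.ndarray) -> PursuitParams:
    return params.replace(**{n: getattr(params, n) + v
                             for n, v in zip(names, values)})


def fit_pursuit(
    data: np.ndarray,
    priors: PursuitParams | None = None,
    free: tuple[str, ...] = ("ln_Pi_s",),
    stimulus: StimulusConfig | None = None,
    fit: FitConfig | None = None,
    observation: ObservationModel | None = None,
) -> PosteriorDensity:
    """Invert one condition's cycle-averaged position error.

    Free parameters are additive offsets from the prior expectations in
    ``priors`` with prior variance 1/2.  Returns the posterior with
    ``names`` matching ``free``.
    """
    priors = priors or PursuitParams()
    fit = fit or FitConfig()
    observation = observation or ObservationModel()
    data = observation.whiten(np.asarray(data, float))
    cache: dict[tuple, np.ndarray] = {}

    def h(theta: np.ndarray) -> np.ndarray:
        key = tuple(np.round(theta, 10))
        if key not in cache:
            try:
                pred = predict_position_error(
                    _apply(priors, free, theta), stimulus, fit=fit
                )
            except Exception:
                # unstable parameter region: a huge residual makes the
                # Levenberg-Marquardt safeguard reject the step
                pred = np.full(len(data), 1e3)
            cache[key] = observation.whiten(pred)
        return cache[key]

    p = len(free)
    theta0 = np.zeros(p)
    if len(fit.init_offsets) > 1:
        sse = []
        for off in fit.init_offsets:
            cand = np.zeros(p)
            cand[0] = off
            sse.append(float(np.sum((data - h(cand)) ** 2)))
        theta0[0] = fit.init_offsets[int(np.argmin(sse))]
    return variational_laplace(
        data, h, np.zeros(p), np.eye(p) * priors.prior_variance,
        max_iter=fit.max_iter, tol=fit.tol, fd_step=fit.fd_step,
        fd_mode=fit.fd_mode, theta0=theta0, names=free,
    )


def fit_conditions(
    smooth_data: np.ndarray,
    noisy_data: np.ndarray,
    effect_model: ConditionEffectModel | None = None,
    priors: PursuitParams | None = None,
    free_shared: tuple[str, ...] = ("ln_Pi_s",),
    stimulus: StimulusConfig | None = None,
    fit: FitConfig | None = None,
) -> PosteriorDensity:
    """Joint inversion of both conditions with condition deltas.

    The parameter vector is [shared offsets..., deltas...]: shared
    offsets apply to both conditions, deltas additionally to the Noisy
    condition for the parameters indicated by ``effect_model``.
    Posterior ``names`` are the shared names followed by
    ``"delta_<name>"`` entries; 90% credible intervals are available
    from the returned density.
    """
    effect_model = effect_model or ConditionEffectModel()
    priors = priors or PursuitParams()
    fit = fit or FitConfig()
    y = np.concatenate([np.asarray(smooth_data, float),
                        np.asarray(noisy_data, float)])
    shared, deltas = free_shared, effect_model.effects
    cache: dict[tuple, np.ndarray] = {}

    def h(theta: np.ndarray) -> np.ndarray:
        key = tuple(np.round(theta, 10))
        if key not in cache:
            th_s = theta[: len(shared)]
            th_d = theta[len(shared):]
            p_smooth = _apply(priors, shared, th_s)
            p_noisy = _apply(p_smooth, deltas, th_d)
            try:
                cache[key] = np.concatenate([
                    predict_position_error(p_smooth, stimulus, fit=fit),
                    predict_position_error(p_noisy, stimulus, fit=fit),
                ])
            except Exception:
                cache[key] = np.full(len(y), 1e3)
        return cache[key]

    p = len(shared) + len(deltas)
    names = tuple(shared) + tuple(f"delta_{n}" for n in deltas)
    return variational_laplace(
        y, h, np.zeros(p), np.eye(p) * priors.prior_variance,
        max_iter=fit.max_iter, tol=fit.tol, fd_step=fit.fd_step,
        fd_mode=fit.fd_mode, names=names,
    )


#: frozen seed base for the Noisy-condition prediction ensemble
_SURFACE_SEED_BASE = 7001
_surface_cache: dict = {}


class PrecisionSurface:
    """Precomputed one-parameter family of position-error predictions.

    The cycle-averaged position error depends, for fixed kinetic and
    prior parameters, only on the sensory log-precision ln Pi_s.  This
    class tabulates the prediction over a grid of ln Pi_s offsets —
    for the Noisy condition as an ensemble mean over frozen stimulus
    realizations (the closed loop responds to each jitter sequence) —
    and serves interpolated predictions, so that inverting one subject
    costs interpolation rather than repeated simulation.  The family is
    subject-independent and is cached per configuration.
    """

    def __init__(
        self,
        condition: str = "smooth",
        priors: PursuitParams | None = None,
        stimulus: StimulusConfig | None = None,
        fit: FitConfig | None = None,
        grid: np.ndarray | None = None,
        n_seeds: int = 12,
    ):
        self.condition = condition
        self.priors = priors or PursuitParams()
        self.fit = fit or FitConfig()
        self.stimulus = stimulus or StimulusConfig(
            cycles_per_trial=self.fit.cycles, dt=self.fit.dt)
        self.grid = (np.arange(-1.2, 2.85, 0.15) if grid is None
                     else np.asarray(grid, float))
        self.n_seeds = n_seeds
        from dataclasses import replace as _rep

        stim = _rep(self.stimulus, cycles_per_trial=self.fit.cycles,
                    dt=self.fit.dt)
        m = int(round(stim.period / self.fit.dt))
        out_grid = np.linspace(0.0, m - 1, self.fit.n_points)
        rows = []
        offsets = []
        for off in self.grid:
            params = self.priors.replace(
                ln_Pi_s=self.priors.ln_Pi_s + float(off))
            if condition == "smooth":
                waves = [self._one(params, stim, None, m, out_grid)]
            else:
                waves = [
                    self._one(params, stim, _SURFACE_SEED_BASE + k, m,
                              out_grid)
                    for k in range(n_seeds)
                ]
            waves = [w for w in waves if w is not None]
            # keep only offsets where the closed loop is stable for a
            # clear majority of stimulus realizations
            if len(waves) > max(1, n_seeds // 2) or (
                condition == "smooth" and waves
            ):
                offsets.append(off)
                rows.append(np.mean(waves, axis=0))
        if len(rows) < 2:
            raise RuntimeError("no stable region for this configuration")
        self.grid = np.array(offsets)
        self.table = np.array(rows)

    def _one(self, params, stim, seed, m, out_grid):
        try:
            res = simulate_pursuit(stim, params, self.condition,
                                   seed=seed, dt=self.fit.dt, noise=None)
        except Exception:
            return None
        n_cyc = len(res.position_error_expected) // m
        folded = res.position_error_expected[: n_cyc * m].reshape(
            n_cyc, m).mean(axis=0)
        return np.interp(out_grid, np.arange(m), folded)

    def predict(self, offset: float) -> np.ndarray:
        """Linearly interpolated prediction at a ln Pi_s offset."""
        g = self.grid
        off = float(np.clip(offset, g[0], g[-1]))
        i = int(np.clip(np.searchsorted(g, off) - 1, 0, len(g) - 2))
        w = (off - g[i]) / (g[i + 1] - g[i])
        return (1.0 - w) * self.table[i] + w * self.table[i + 1]


def precision_surface(
    condition: str,
    priors: PursuitParams | None = None,
    stimulus: StimulusConfig | None = None,
    fit: FitConfig | None = None,
    n_seeds: int = 12,
) -> PrecisionSurface:
    """Cached :class:`PrecisionSurface` for a configuration."""
    priors = priors or PursuitParams()
    fit = fit or FitConfig()
    stimulus = stimulus or StimulusConfig(cycles_per_trial=fit.cycles,
                                          dt=fit.dt)
    key = (condition, tuple(sorted(priors.to_dict().items())),
           stimulus.period, stimulus.amplitude, stimulus.phase_offset,
           stimulus.occluder_interval, stimulus.phase_noise_model,
           stimulus.phase_noise_sd, stimulus.phase_noise_tau,
           stimulus.noise_variance,
           fit.dt, fit.cycles, fit.n_points, n_seeds)
    if key not in _surface_cache:
        _surface_cache[key] = PrecisionSurface(
            condition, priors, stimulus, fit, n_seeds=n_seeds)
    return _surface_cache[key]


def fit_precision(
    data: np.ndarray,
    surface: PrecisionSurface,
    priors: PursuitParams | None = None,
) -> PosteriorDensity:
    """Invert the sensory log-precision against a response surface.

    Variational Laplace over the single ln Pi_s offset, with the
    surface supplying (interpolated) predictions; the coarse surface
    grid also initialises the ascent in the best basin, which matters
    because the waveform's dependence on ln Pi_s is not monotone in
    mean square.
    """
    priors = priors or surface.priors
    y = np.asarray(data, float)
    fitc = surface.fit

    def h(theta: np.ndarray) -> np.ndarray:
        return surface.predict(float(theta[0]))

    # multi-start over local minima of the misfit profile: the
    # waveform family is multimodal in the offset, so ascend from each
    # candidate basin and keep the highest-evidence solution
    sse = np.sum((surface.table - y) ** 2, axis=1)
    is_min = np.r_[True, sse[1:] < sse[:-1]] & \
        np.r_[sse[:-1] < sse[1:], True]
    starts = surface.grid[is_min]
    order = np.argsort(sse[is_min])
    starts = starts[order[:3]]
    best = None
    for s0 in starts:
        post = variational_laplace(
            y, h, np.zeros(1), np.eye(1) * priors.prior_variance,
            max_iter=fitc.max_iter, tol=fitc.tol, fd_step=0.05,
            fd_mode="forward", theta0=np.array([s0]),
            names=("ln_Pi_s",),
        )
        if best is None or post.free_energy > best.free_energy:
            best = post
    return best


def precision_change_factor(delta_log_scaling: float) -> float:
    """Multiplicative precision change implied by a log-scaling delta.

    Parameters scale standard deviations, so a condition delta on a
    log-precision parameter changes the precision itself by the
    *squared* exponential: a delta of 1.57 corresponds to a
    exp(1.57)^2 ~ 23-fold change in sensory precision.
    """
    return float(np.exp(delta_log_scaling) ** 2)


def default_effect_models() -> list[ConditionEffectModel]:
    """The 8-model space: condition effects on every subset of the
    {kinetic, precision, prior} parameter groups."""
    groups = {
        "kinetic": ("theta1", "theta3"),
        "precision": ("ln_Pi_s", "ln_Pi_x", "ln_Pi_v"),
        "prior": ("theta7", "theta8"),
    }
    keys = list(groups)
    out = []
    for mask in range(8):
        effects: tuple[str, ...] = ()
        for b, k in enumerate(keys):
            if mask >> b & 1:
                effects = effects + groups[k]
        out.append(ConditionEffectModel(effects) if effects
                   else ConditionEffectModel(()))
    return out
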