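"""The generative process: target, occluder, retina and oculomotor plant.

The "real world" that the pursuit agent samples.  A target moves
sinusoidally along a horizontal path (optionally with a Gaussian
random-walk perturbation of its phase), part of the path is hidden
behind an occluder, and a bank of 17 Gaussian receptive fields converts
the gaze-to-target angle into retinal channel activations.  The eye is a
first-order plant whose velocity is driven by action.

All positions are in normalized units (path half-extent = 1); the
recorded visual-angle geometry is retained only as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StimulusConfig",
    "RetinaModel",
    "WorldState",
    "target_position",
    "phase_walk_increments",
    "phase_noise_series",
    "occluder_value",
    "retinal_input",
    "world_step",
    "write_trial_tsv",
]

#: descriptive metadata only -- the model works in normalized units
PATH_EXTENT_DEG = 37.0
AMPLITUDE_DEG = 18.5


@dataclass
class StimulusConfig:
    """Stimulus geometry and timing.

    The target traverses ``amplitude * cos(2*pi*t/period + phase_offset)``.
    With the default ``phase_offset = pi`` the trial starts at the left
    extreme of the path (-amplitude), matching the presentation protocol;
    the occluder covers the segment between the midline and the furthest
    10% of the path from the start, i.e. 40% of the total path.

    ``noise_variance`` is the per-millisecond variance of the Gaussian
    random walk added to the phase in the Noisy condition.
    """

    period: float = 3.94
    amplitude: float = 1.0
    phase_offset: float = np.pi
    occluder_interval: tuple[float, float] = (0.0, 0.8)
    noise_variance: float = float(np.exp(-0.5))
    dt: float = 0.001
    cycles_per_trial: int = 3
    #: phase-noise process for closed-loop simulation: "ou" keeps the
    #: jitter bounded (mean-reverting, stationary SD ``phase_noise_sd``
    #: rad with correlation time ``phase_noise_tau`` s) so the noisy
    #: target still fluctuates rapidly around a trackable sinusoid;
    #: "walk" accumulates raw increments of variance ``noise_variance``
    #: per ms
    phase_noise_model: str = "ou"
    phase_noise_sd: float = 0.8
    phase_noise_tau: float = 0.01

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        lo, hi = self.occluder_interval
        if not (-self.amplitude <= lo <= hi <= self.amplitude):
            raise ValueError("occluder_interval must lie within the path")
        if self.phase_noise_model not in ("ou", "walk"):
            raise ValueError("phase_noise_model must be 'ou' or 'walk'")

    @property
    def trial_duration(self) -> float:
        return self.period * self.cycles_per_trial


@dataclass
class RetinaModel:
    """Bank of 17 Gaussian receptive fields tiling retinotopic angle."""

    centers: np.ndarray = field(
        default_factory=lambda: np.linspace(-1.5, 1.5, 17)
    )
    width: float = 1.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (17,):
            raise ValueError("retina must have exactly 17 receptive fields")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass
class WorldState:
    """Hidden states of the generative process."""

    x_o: float = 0.0
    x_o_dot: float = 0.0
    v: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if not all(
            np.isfinite([self.x_o, self.x_o_dot, self.v, self.t])
        ):
            raise ValueError("world state must be finite")


def phase_walk_increments(
    n: int, config: StimulusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw phase-walk increments for ``n`` simulation steps.

    The walk variance is tied to a 1 ms step; coarser or finer step
    sizes rescale the per-step variance proportionally so the walk's
    diffusion rate is invariant to dt.
    """
    per_step = config.noise_variance * (config.dt / 0.001)
    return rng.normal(0.0, np.sqrt(per_step), size=n)


def phase_noise_series(
    n: int, config: StimulusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Phase-perturbation series for a noisy-condition trial.

    "walk": cumulative sum of per-ms-variance increments (the literal
    random walk).  "ou": a mean-reverting process with the same rapid
    fluctuations but bounded excursion, so the ensemble-average target
    path remains the underlying sinusoid.
    """
    if config.phase_noise_model == "walk":
        return np.cumsum(phase_walk_increments(n, config, rng))
    alpha = float(np.exp(-config.dt / max(config.phase_noise_tau, 1e-9)))
    innov_sd = config.phase_noise_sd * np.sqrt(1.0 - alpha**2)
    out = np.empty(n)
    x = rng.normal(0.0, config.phase_noise_sd)
    for i in range(n):
        x = alpha * x + innov_sd * rng.standard_normal()
        out[i] = x
    return out


def target_position(
    t: float | np.ndarray,
    condition: str = "smooth",
    phase_walk: float | np.ndarray = 0.0,
    config: StimulusConfig | None = None,
) -> float | np.ndarray:
    """Target position at time ``t`` (seconds).

    Smooth: amplitude * cos(2 pi t / period + phase_offset).
    Noisy: the same with the accumulated phase walk added; the caller
    threads the walk state (see :func:`phase_walk_increments`).
    """
    if config is None:
        config = StimulusConfig()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if condition not in ("smooth", "noisy"):
        raise ValueError(f"unknown condition {condition!r}")
    phase = 2.0 * np.pi * t / config.period + config.phase_offset
    if condition == "noisy":
        phase = phase + np.asarray(phase_walk, dtype=float)
    out = config.amplitude * np.cos(phase)
    return float(out) if out.ndim == 0 else out


def occluder_value(
    v: float | np.ndarray, config: StimulusConfig | None = None
) -> int | np.ndarray:
    """1 when the position ``v`` is visible, 0 when occluded."""
    if config is None:
        config = StimulusConfig()
    lo, hi = config.occluder_interval
    v = np.asarray(v, dtype=float)
    occluded = (v > lo) & (v <= hi)
    out = np.where(occluded, 0, 1)
    return int(out) if out.ndim == 0 else out


def retinal_input(
    x_o: float,
    v: float,
    retina: RetinaModel | None = None,
    config: StimulusConfig | None = None,
) -> np.ndarray:
    """Activation of the 17 receptive fields for gaze x_o and target v.

    Channel i responds as O(v) * exp(-(r_i + x_o - v)^2 / width^2): all
    channels are silenced while the target is behind the occluder.
    """
    if retina is None:
        retina = RetinaModel()
    o = occluder_value(v, config)
    d = retina.centers + x_o - v
    return o * np.exp(-(d**2) / retina.width**2)


def world_step(
    state: WorldState,
    action: float,
    noise_draws: tuple[float, float] = (0.0, 0.0),
    dt: float = 0.001,
) -> WorldState:
    """Euler update of the oculomotor plant.

    d x_o / dt = x_o';  d x_o' / dt = a - x_o' + omega_x.
    ``noise_draws`` = (omega_s, omega_x); the sensory noise omega_s does
    not enter the state, it is added by the caller when sampling.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(action):
        raise ValueError("action must be finite")
    _, omega_x = noise_draws
    return WorldState(
        x_o=state.x_o + dt * state.x_o_dot,
        x_o_dot=state.x_o_dot + dt * (action - state.x_o_dot + omega_x),
        v=state.v,
        t=state.t + dt,
    )


def write_trial_tsv(path, result, condition: str, trial: int = 0) -> None:
    """Write one simulated trial as tidy TSV (stimulus_world contract)."""
    cfg = result.config
    cycle = np.floor(result.time / cfg.period).astype(int)
    frame = pd.DataFrame(
        {
            "time_s": result.time,
            "target_pos": result.target,
            "occluded": 1 - result.visible,
            "eye_pos": result.eye,
            "eye_vel": result.eye_vel,
            "condition": condition,
            "trial": trial,
            "cycle": cycle,
        }
    )
    frame.to_csv(path, sep="\t", index=False)
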