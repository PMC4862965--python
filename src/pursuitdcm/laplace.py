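"""Variational Laplace inversion of nonlinear time-series models.

Fits y = h(theta) + e, with e ~ N(0, exp(-gamma) I) and Gaussian priors
over theta, by Gauss-Newton ascent on the (Laplace approximation to
the) variational free energy.  The free energy returned with the
posterior approximates the log model evidence and splits into accuracy
and complexity, so fitted models can be compared and averaged by their
evidence.

The same engine inverts the behavioural pursuit model and the
canonical-microcircuit network; its conjugate (linear-Gaussian) limit
reproduces the closed-form Bayesian linear regression posterior, which
is the engine's primary correctness check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PosteriorDensity",
    "variational_laplace",
    "bayesian_model_average",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PosteriorDensity:
    """Gaussian posterior over parameters with its free energy.

    ``free_energy`` approximates the log model evidence; ``gamma`` is
    the posterior log-precision of observation noise; ``trace`` records
    the free energy of accepted iterations (non-decreasing).
    """

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    gamma: float
    trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    names: tuple = ()

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def credible_interval(self, level: float = 0.90) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        sd = self.sd()
        return np.stack([self.mean - z * sd, self.mean + z * sd], axis=1)


def _jacobian(h: Callable, theta: np.ndarray, y_len: int,
              step: float | np.ndarray, mode: str = "central",
              f0: np.ndarray | None = None) -> np.ndarray:
    """Finite-difference Jacobian of h at theta.

    ``central`` differences by default; ``forward`` reuses the base
    prediction ``f0`` and halves the number of model evaluations (used
    when each evaluation is a simulation).
    """
    p = len(theta)
    steps = np.broadcast_to(np.asarray(step, float), (p,))
    J = np.empty((y_len, p))
    if mode == "forward":
        if f0 is None:
            f0 = h(theta)
        for i in range(p):
            d = np.zeros(p)
            d[i] = steps[i]
            J[:, i] = (h(theta + d) - f0) / steps[i]
    else:
        for i in range(p):
            d = np.zeros(p)
            d[i] = steps[i]
            J[:, i] = (h(theta + d) - h(theta - d)) / (2.0 * steps[i])
    return J


def variational_laplace(
    data: np.ndarray,
    h: Callable[[np.ndarray], np.ndarray],
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    *,
    noise_log_precision: float | None = None,
    gamma_prior: tuple[float, float] = (0.0, 16.0),
    max_iter: int = 32,
    tol: float = 1e-2,
    fd_step: float | np.ndarray = 1e-3,
    fd_mode: str = "central",
    theta0: np.ndarray | None = None,
    names: Sequence[str] = (),
) -> PosteriorDensity:
    """Gauss-Newton / Laplace optimisation of free energy.

    ``h`` maps a parameter vector to a prediction of ``data``.  If
    ``noise_log_precision`` is given the observation noise is fixed;
    otherwise its log precision gamma is estimated under a Gaussian
    hyperprior ``gamma_prior`` = (mean, variance).  Accepted iterations
    never decrease the free energy (Levenberg-Marquardt safeguard);
    convergence when the free-energy gain drops below ``tol`` nats.

    Returns the posterior density; warns (rather than failing) on
    non-convergence, and ridge-regularises singular curvature.
    """
    y = np.asarray(data, float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("data must be finite")
    eta = np.asarray(prior_mean, float).ravel()
    Sp = np.atleast_2d(np.asarray(prior_cov, float))
    if Sp.shape == (1, 1) and eta.size > 1:
        Sp = Sp[0, 0] * np.eye(eta.size)
    Pp = np.linalg.inv(Sp)
    n, p = y.size, eta.size
    fit_gamma = noise_log_precision is None
    g0, vg = gamma_prior

    theta = eta.copy() if theta0 is None else np.asarray(theta0, float).copy()
    gamma = g0 if fit_gamma else float(noise_log_precision)
    lam = 1e-6  # LM ridge
    trace: list[float] = []

    def free_energy(th, gm, pred, Sq=None):
        r = y - pred
        F = (-0.5 * np.exp(gm) * (r @ r) + 0.5 * n * gm - 0.5 * n * _LOG2PI)
        d = th - eta
        F += -0.5 * d @ Pp @ d
        if fit_gamma:
            F += -0.5 * (gm - g0) ** 2 / vg
        if Sq is not None:
            # Gaussian-entropy / complexity terms of the Laplace bound
            sign, logdet_q = np.linalg.slogdet(Sq)
            _, logdet_p = np.linalg.slogdet(Sp)
            F += 0.5 * (logdet_q - logdet_p)
            if fit_gamma:
                F += 0.5 * np.log(max(Sq_gamma_var(gm, r), 1e-12) / vg)
        return float(F)

    def Sq_gamma_var(gm, r):
        return 1.0 / (0.5 * np.exp(gm) * (r @ r) + 1.0 / vg)

    pred = h(theta)
    F_old = free_energy(theta, gamma, pred)
    trace.append(F_old)
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        J = _jacobian(h, theta, n, fd_step, fd_mode, f0=pred)
        r = y - pred

        if fit_gamma:
            # conditional maximisation of F over the noise log-precision
            # (clipped Newton: globally convergent for this concave 1-d
            # objective, immune to far-start overshoot)
            gamma_new = gamma
            for _ in range(32):
                gdot = -0.5 * np.exp(gamma_new) * (r @ r) + 0.5 * n \
                    - (gamma_new - g0) / vg
                gcurv = 0.5 * np.exp(gamma_new) * (r @ r) + 1.0 / vg
                step_g = float(np.clip(gdot / gcurv, -1.0, 1.0))
                gamma_new += step_g
                if abs(step_g) < 1e-8:
                    break
            gamma_new = float(np.clip(gamma_new, -16.0, 16.0))
            F_g = free_energy(theta, gamma_new, pred)
            if F_g >= F_old - 1e-9:
                gamma, F_old = gamma_new, F_g
                trace.append(F_old)

        e_g = np.exp(gamma)
        H = e_g * (J.T @ J) + Pp
        g = e_g * (J.T @ r) - Pp @ (theta - eta)

        accepted = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(H + lam * np.eye(p), g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-4)
                continue
            cand = theta + delta
            pred_c = h(cand)
            F_c = free_energy(cand, gamma, pred_c)
            if np.isfinite(F_c) and F_c >= F_old - 1e-9:
                accepted = True
                break
            lam = max(lam * 10.0, 1e-4)
        if not accepted:
            break
        gain = F_c - F_old
        theta, pred, F_old = cand, pred_c, F_c
        trace.append(F_old)
        lam = max(lam / 10.0, 1e-6)
        if gain < tol:
            converged = True
            break

    if not converged and it == max_iter:
        warnings.warn(
            "variational_laplace: free energy still improving at max_iter",
            RuntimeWarning,
            stacklevel=2,
        )

    J = _jacobian(h, theta, n, fd_step, fd_mode, f0=pred)
    H = np.exp(gamma) * (J.T @ J) + Pp
    try:
        Sq = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Sq = np.linalg.inv(H + 1e-8 * np.eye(p))
    Sq = 0.5 * (Sq + Sq.T)
    F_final = free_energy(theta, gamma, pred, Sq=Sq)

    return PosteriorDensity(
        mean=theta,
        cov=Sq,
        free_energy=F_final,
        gamma=gamma,
        trace=trace,
        converged=converged,
        n_iter=it,
        names=tuple(names),
    )


def bayesian_model_average(
    fits: Sequence[PosteriorDensity],
) -> PosteriorDensity:
    """Average parameter posteriors over models, weighted by evidence.

    Weights are softmax of the free energies (posterior model
    probabilities under a flat model prior); the averaged density is
    moment-matched to the Gaussian mixture.  All fits must share a
    parameter space.
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    F = np.array([f.free_energy for f in fits])
    w = np.exp(F - F.max())
    w /= w.sum()
    mean = sum(wi * f.mean for wi, f in zip(w, fits))
    cov = sum(
        wi * (f.cov + np.outer(f.mean - mean, f.mean - mean))
        for wi, f in zip(w, fits)
    )
    return PosteriorDensity(
        mean=mean,
        cov=cov,
        free_energy=float(np.log(np.sum(np.exp(F - F.max()))) + F.max()),
        gamma=float(sum(wi * f.gamma for wi, f in zip(w, fits))),
        names=fits[0].names,
    )
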