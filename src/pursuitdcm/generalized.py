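"""Generalized coordinates of motion.

A variable in generalized coordinates is represented together with its
temporal derivatives up to a fixed embedding order: (x, x', x'', ...).
This gives a Bayesian filter an implicit model of the recent past and
near future, and is the state representation shared by the world
simulator, the subjective pursuit model and the filtering scheme.

Analytic (infinitely differentiable) random fluctuations are summarised
by a temporal smoothness model: a Gaussian autocorrelation of the noise
induces a well-defined covariance between the noise and its derivatives,
from which a precision over generalized orders is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneralizedVector",
    "SmoothnessModel",
    "shift_operator",
    "embed_series",
    "generalized_precision",
]


@dataclass
class GeneralizedVector:
    """A set of variables with their temporal derivatives.

    values[i, k] is the k-th temporal derivative of variable i;
    column 0 is the value itself, column 1 the velocity, and so on.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be a base_dim x order matrix")
        if self.values.shape[1] < 1:
            raise ValueError("embedding order must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("generalized coordinates must be finite")

    @property
    def base_dim(self) -> int:
        return self.values.shape[0]

    @property
    def order(self) -> int:
        return self.values.shape[1]

    def shifted(self) -> "GeneralizedVector":
        """Apply the derivative (shift) operator along the order axis."""
        return GeneralizedVector(self.values @ shift_operator(self.order).T)


@dataclass
class SmoothnessModel:
    """Temporal smoothness of analytic random fluctuations.

    ``correlation_scale`` is the width (in time units) of the Gaussian
    autocorrelation exp(-h^2 / (2 s^2)) assumed for the fluctuations.
    Smaller scales mean rougher noise and weaker coupling between
    derivative orders.
    """

    correlation_scale: float = 0.5
    order: int = 1

    def __post_init__(self) -> None:
        if self.correlation_scale <= 0:
            raise ValueError("correlation_scale must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def covariance(self) -> np.ndarray:
        """Covariance of (w, w', w'', ...) for unit-variance fluctuations.

        For a stationary process with autocorrelation rho(h),
        cov(w^(i), w^(j)) = (-1)^i * rho^(i+j)(0) when i + j is even and
        0 otherwise.  For the Gaussian kernel rho(h) = exp(-h^2/(2 s^2)),
        rho^(2k)(0) = (-1)^k (2k-1)!! / s^(2k).
        """
        n = self.order
        s2 = self.correlation_scale**2
        cov = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if (i + j) % 2:
                    continue
                k = (i + j) // 2
                # (-1)^i * (-1)^k (2k-1)!! / s^(2k)
                dfact = 1.0
                for m in range(1, 2 * k, 2):
                    dfact *= m
                cov[i, j] = (-1.0) ** (i + k) * dfact / s2**k
        return cov


def shift_operator(order: int) -> np.ndarray:
    """Matrix form of d/dt on the order axis of a generalized vector.

    Maps (x, x', ..., x^(n-1)) to (x', x'', ..., x^(n-1), 0).
    The operator is nilpotent: its ``order``-th power vanishes.
    """
    if int(order) != order or order < 1:
        raise ValueError("order must be a positive integer")
    order = int(order)
    return np.eye(order, k=1)


def embed_series(
    samples: np.ndarray,
    dt: float,
    order: int,
    at_index: int,
    window: int | None = None,
) -> GeneralizedVector:
    """Estimate a sampled signal and its derivatives at one index.

    A local least-squares polynomial of degree ``order - 1`` is fitted
    over a symmetric window around ``at_index``; its derivatives at the
    centre are returned.  Exact for polynomials of degree < order.
    """
    samples = np.asarray(samples, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if int(order) != order or order < 1:
        raise ValueError("order must be a positive integer")
    order = int(order)
    n = samples.shape[0]
    if window is None:
        window = max(order, 3) if order > 1 else 1
    half = window // 2
    lo = max(0, at_index - half)
    hi = min(n, at_index + half + 1)
    if hi - lo < order:
        raise ValueError(
            f"need at least {order} samples around index {at_index}, have {hi - lo}"
        )
    t = (np.arange(lo, hi) - at_index) * dt
    # Vandermonde in the monomial basis t^k / k!: coefficients are the
    # derivatives themselves.
    basis = np.stack(
        [t**k / float(math.factorial(k)) for k in range(order)], axis=1
    )
    coef, *_ = np.linalg.lstsq(basis, samples[lo:hi], rcond=None)
    return GeneralizedVector(coef[np.newaxis, :])


def generalized_precision(
    base_log_precision: float, smoothness: SmoothnessModel
) -> np.ndarray:
    """Precision over generalized orders of a fluctuation.

    The base (order-0) fluctuation has precision exp(base_log_precision);
    higher orders inherit the serial-correlation structure implied by the
    smoothness model.  The result is symmetric positive definite and
    scales multiplicatively with the base precision.
    """
    cov = smoothness.covariance()
    prec = np.linalg.inv(cov)
    prec = 0.5 * (prec + prec.T)
    return float(np.exp(base_log_precision)) * prec
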