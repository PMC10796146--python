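"""Synthetic data and instance generators.

Everything here is generated programmatically and reproducible from its
spec/seed: chaotic Lorenz trajectories for the training tasks, random sparse
matrices for operator oracles, and random linear systems for analyzer
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .integrators import ode_step
from .sparse import CSRMatrix

__all__ = [
    "LorenzSpec",
    "lorenz_series",
    "random_csr",
    "random_linear_system",
]


@dataclass(frozen=True)
class LorenzSpec:
    """Lorenz system parameters; the defaults sit in the chaotic regime.

    ``seed`` jitters the initial state slightly so that different seeds give
    different trajectories on the same attractor.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 0.01
    duration: float = 60.0
    initial: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.02:
            raise ParameterError("dt must lie in (0, 0.02] for rk4 stability")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")


def lorenz_series(spec: LorenzSpec = LorenzSpec()) -> np.ndarray:
    """RK4-integrated Lorenz trajectory ``[T x 3]``, deterministic per spec."""

    def rhs(t, y):
        x, yy, z = y
        return np.array([
            spec.sigma * (yy - x),
            x * (spec.rho - z) - yy,
            x * yy - spec.beta * z,
        ])

    rng = np.random.default_rng(spec.seed)
    y = np.asarray(spec.initial, dtype=float) + 1e-3 * rng.standard_normal(3)
    n = int(round(spec.duration / spec.dt))
    out = np.empty((n, 3))
    for i in range(n):
        y = ode_step(rhs, y, i * spec.dt, spec.dt, method="rk4")
        if not np.all(np.isfinite(y)):
            raise ParameterError(f"Lorenz integration diverged at step {i}")
        out[i] = y
    return out


def random_csr(n_pre: int, n_post: int, density: float, seed: int,
               weight_law: str = "normal") -> CSRMatrix:
    """Reproducible random sparse matrix for operator oracles."""
    if not (0.0 <= density <= 1.0):
        raise ParameterError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_pre, n_post)) < density
    if weight_law == "normal":
        vals = rng.standard_normal((n_pre, n_post))
    elif weight_law == "uniform":
        vals = rng.uniform(0.0, 1.0, (n_pre, n_post))
    elif weight_law == "ones":
        vals = np.ones((n_pre, n_post))
    else:
        raise ParameterError(f"unknown weight law {weight_law!r}")
    return CSRMatrix.from_dense(np.where(mask, vals, 0.0))


def random_linear_system(dim: int, spectral_bound: float, seed: int):
    """Random ``(A, b)`` with ``max |eigenvalue(A)| <= spectral_bound``."""
    if spectral_bound <= 0:
        raise ParameterError("spectral bound must be positive")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((dim, dim))
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    A = A * (spectral_bound / radius)
    b = rng.standard_normal(dim)
    return A, b
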