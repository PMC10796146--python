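"""Numerical steppers for ODEs and SDEs.

The explicit Runge–Kutta family is driven by Butcher tableaus, so new schemes
are added by registering a tableau rather than writing a new stepper.  The
exponential Euler scheme treats the linear part of ``dy/dt = a*y + r(t, y)``
exactly and is therefore exact (to round-off) on linear equations — the
workhorse for membrane and gating equations.  SDE steppers take externally
drawn Wiener increments so that pathwise comparisons (Itô vs Stratonovich,
strong-order studies) can reuse a common noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError, StiffnessError, TableauError

__all__ = [
    "ODESystem",
    "SDESystem",
    "ButcherTableau",
    "SolverSpec",
    "TABLEAUS",
    "register_tableau",
    "get_tableau",
    "ode_step",
    "exp_euler_step",
    "adaptive_step",
    "integrate_adaptive",
    "sde_step",
]


@dataclass(frozen=True)
class ODESystem:
    """Right-hand side ``f(t, y) -> dy/dt`` with a state dimension."""

    f: Callable
    dim: int


@dataclass(frozen=True)
class SDESystem:
    """Drift ``f(t, y)`` and diffusion ``g(t, y)`` with integral convention.

    ``integral_type`` is ``"ito"`` or ``"stratonovich"``; ``wiener_type`` is
    ``"scalar"`` (``g`` returns the shape of ``y``) or ``"multi"`` (``g``
    returns one column per independent Wiener increment).
    """

    f: Callable
    g: Callable
    integral_type: str = "ito"
    wiener_type: str = "scalar"

    def __post_init__(self):
        if self.integral_type not in ("ito", "stratonovich"):
            raise ParameterError(f"unknown integral type {self.integral_type!r}")
        if self.wiener_type not in ("scalar", "multi"):
            raise ParameterError(f"unknown wiener type {self.wiener_type!r}")


@dataclass(frozen=True)
class ButcherTableau:
    """Coefficients of an explicit Runge–Kutta scheme.

    ``A`` is the strictly lower-triangular stage matrix, ``b`` the output
    weights, ``c`` the stage nodes, ``order`` the classical order.  ``b_hat``
    optionally holds embedded lower-order weights for error estimation.
    """

    A: tuple
    b: tuple
    c: tuple
    order: int
    b_hat: tuple | None = None
    name: str = ""

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        b = np.asarray(self.b, dtype=float)
        c = np.asarray(self.c, dtype=float)
        s = len(b)
        if A.shape != (s, s) or c.shape != (s,):
            raise TableauError("tableau dimensions inconsistent")
        if abs(b.sum() - 1.0) > 1e-12:
            raise TableauError(f"output weights must sum to 1, got {b.sum()!r}")
        if np.any(np.triu(A) != 0.0):
            raise TableauError("explicit tableau requires strictly lower-triangular A")
        if np.max(np.abs(A.sum(axis=1) - c)) > 1e-12:
            raise TableauError("stage nodes must satisfy c_i = sum_j A_ij")
        if self.b_hat is not None and len(self.b_hat) != s:
            raise TableauError("embedded weights must match the stage count")

    @property
    def n_stages(self) -> int:
        return len(self.b)


@dataclass(frozen=True)
class SolverSpec:
    """Named solver plus step-size settings (adaptive fields optional)."""

    method: str
    dt: float
    rtol: float = 1e-6
    atol: float = 1e-9
    dt_min: float = 1e-8
    dt_max: float = np.inf

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not (self.dt_min <= self.dt <= self.dt_max):
            raise ParameterError("need dt_min <= dt <= dt_max")


def _tab(name, A, b, c, order, b_hat=None):
    return ButcherTableau(
        A=tuple(tuple(row) for row in A),
        b=tuple(b),
        c=tuple(c),
        order=order,
        b_hat=tuple(b_hat) if b_hat is not None else None,
        name=name,
    )


TABLEAUS: dict[str, ButcherTableau] = {}


def register_tableau(name: str, tableau: ButcherTableau, overwrite: bool = False) -> None:
    """Add a scheme to the registry; ``ode_step`` can then use it by name."""
    if name in TABLEAUS and not overwrite:
        raise ParameterError(f"tableau {name!r} already registered")
    TABLEAUS[name] = tableau


def get_tableau(name: str) -> ButcherTableau:
    try:
        return TABLEAUS[name]
    except KeyError:
        raise ParameterError(
            f"unknown method {name!r}; available: {sorted(TABLEAUS)}"
        ) from None


register_tableau("euler", _tab("euler", [[0.0]], [1.0], [0.0], order=1))
register_tableau(
    "midpoint",
    _tab("midpoint", [[0, 0], [0.5, 0]], [0.0, 1.0], [0.0, 0.5], order=2),
)
register_tableau(
    "heun", _tab("heun", [[0, 0], [1.0, 0]], [0.5, 0.5], [0.0, 1.0], order=2)
)
TABLEAUS["rk2"] = TABLEAUS["midpoint"]
register_tableau(
    "rk3",
    _tab(
        "rk3",
        [[0, 0, 0], [0.5, 0, 0], [-1.0, 2.0, 0]],
        [1 / 6, 2 / 3, 1 / 6],
        [0.0, 0.5, 1.0],
        order=3,
    ),
)
register_tableau(
    "rk4",
    _tab(
        "rk4",
        [[0, 0, 0, 0], [0.5, 0, 0, 0], [0, 0.5, 0, 0], [0, 0, 1.0, 0]],
        [1 / 6, 1 / 3, 1 / 3, 1 / 6],
        [0.0, 0.5, 0.5, 1.0],
        order=4,
    ),
)
# Fehlberg 4(5) embedded pair: b holds the 5th-order weights (propagated
# solution), b_hat the 4th-order weights used for the error estimate.
register_tableau(
    "rkf45",
    _tab(
        "rkf45",
        [
            [0, 0, 0, 0, 0, 0],
            [1 / 4, 0, 0, 0, 0, 0],
            [3 / 32, 9 / 32, 0, 0, 0, 0],
            [1932 / 2197, -7200 / 2197, 7296 / 2197, 0, 0, 0],
            [439 / 216, -8, 3680 / 513, -845 / 4104, 0, 0],
            [-8 / 27, 2, -3544 / 2565, 1859 / 4104, -11 / 40, 0],
        ],
        [16 / 135, 0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55],
        [0, 1 / 4, 3 / 8, 12 / 13, 1, 1 / 2],
        order=5,
        b_hat=[25 / 216, 0, 1408 / 2565, 2197 / 4104, -1 / 5, 0],
    ),
)


def _rk_stages(f, y, t, dt, tableau):
    A = np.asarray(tableau.A)
    c = np.asarray(tableau.c)
    k = []
    for i in range(tableau.n_stages):
        yi = y
        for j in range(i):
            if A[i, j] != 0.0:
                yi = yi + dt * A[i, j] * k[j]
        k.append(np.asarray(f(t + c[i] * dt, yi), dtype=float))
    return k


def ode_step(f, y, t: float, dt: float, method="rk4"):
    """One explicit Runge–Kutta step of the named scheme (or a tableau)."""
    tableau = method if isinstance(method, ButcherTableau) else get_tableau(method)
    y = np.asarray(y, dtype=float)
    k = _rk_stages(f, y, t, dt, tableau)
    out = y.copy()
    for bi, ki in zip(tableau.b, k):
        if bi != 0.0:
            out = out + dt * bi * ki
    return out


def _phi1(z):
    """(e^z - 1)/z evaluated stably; Taylor series below |z| = 1e-8."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-8
    safe = np.where(small, 1.0, z)
    out = np.where(small, 1.0 + z / 2.0 + z * z / 6.0, np.expm1(safe) / safe)
    return out


def exp_euler_step(a, r, y, t: float, dt: float):
    """Exponential Euler for ``dy/dt = a*y + r(t, y)``.

    ``a`` is the (scalar or per-component) linear coefficient; ``r`` is the
    residual, either a callable ``r(t, y)`` or a precomputed array.  The step
    is ``y * e^{a dt} + dt * phi1(a dt) * r``, exact for constant ``r`` and
    degrading gracefully to forward Euler as ``a -> 0``.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    rv = np.asarray(r(t, y) if callable(r) else r, dtype=float)
    z = a * dt
    return y * np.exp(z) + dt * _phi1(z) * rv


def adaptive_step(f, y, t: float, dt: float, spec: SolverSpec, method="rkf45"):
    """One trial step of an embedded Runge–Kutta pair.

    Returns ``(y_new, t_new, dt_next, accepted)``.  The error estimate is the
    RMS of the high/low-order difference scaled by ``atol + rtol*|y|``; steps
    with estimate <= 1 are accepted.  The next step size follows the standard
    safety-factor power law (safety 0.9, growth clamped to [0.2, 5]), clipped
    to ``[dt_min, dt_max]``.  A rejected step at ``dt_min`` raises
    :class:`StiffnessError`.
    """
    tableau = method if isinstance(method, ButcherTableau) else get_tableau(method)
    if tableau.b_hat is None:
        raise ParameterError(f"method {tableau.name!r} has no embedded error weights")
    y = np.asarray(y, dtype=float)
    k = _rk_stages(f, y, t, dt, tableau)
    y_hi = y.copy()
    y_lo = y.copy()
    for bi, bhi, ki in zip(tableau.b, tableau.b_hat, k):
        y_hi = y_hi + dt * bi * ki
        y_lo = y_lo + dt * bhi * ki
    scale = spec.atol + spec.rtol * np.maximum(np.abs(y), np.abs(y_hi))
    err = float(np.sqrt(np.mean(((y_hi - y_lo) / scale) ** 2)))
    accepted = err <= 1.0
    if err == 0.0:
        factor = 5.0
    else:
        factor = min(5.0, max(0.2, 0.9 * err ** (-1.0 / tableau.order)))
    dt_next = float(np.clip(dt * factor, spec.dt_min, spec.dt_max))
    if not accepted and dt <= spec.dt_min:
        raise StiffnessError(
            f"step rejected at dt_min={spec.dt_min} (error estimate {err:.3g}); "
            "the problem appears too stiff for this explicit method"
        )
    if accepted:
        return y_hi, t + dt, dt_next, True
    return y, t, dt_next, False


def integrate_adaptive(f, y0, t_span, spec: SolverSpec, method="rkf45", max_steps=100000):
    """Integrate over ``t_span`` with the adaptive controller; returns (ts, ys)."""
    t0, t1 = t_span
    t, y, dt = float(t0), np.asarray(y0, dtype=float), spec.dt
    ts, ys = [t], [y]
    for _ in range(max_steps):
        if t >= t1:
            break
        dt = min(dt, t1 - t)
        y_new, t_new, dt, ok = adaptive_step(f, y, t, dt, spec, method)
        if ok:
            t, y = t_new, y_new
            ts.append(t)
            ys.append(y)
    else:
        raise StiffnessError("adaptive integration exceeded max_steps")
    return np.asarray(ts), np.asarray(ys)


def _diffusion_derivative(g, t, y, h=1e-6):
    """Diagonal derivative dg_i/dy_i by central differences (scalar noise)."""
    y = np.asarray(y, dtype=float)
    step = h * (1.0 + np.abs(y))
    return (np.asarray(g(t, y + step)) - np.asarray(g(t, y - step))) / (2.0 * step)


def sde_step(system: SDESystem, y, t: float, dt: float, dW, method="euler_maruyama"):
    """One fixed-step SDE update using externally drawn Wiener increments.

    ``dW`` must have variance ``dt`` per Wiener component; drawing it outside
    the stepper keeps paths reproducible and lets Itô/Stratonovich schemes be
    compared on common noise.  Methods:

    - ``euler_maruyama``: Itô; ``y + f dt + g dW``.
    - ``milstein``: Itô, scalar noise only; adds ``0.5 g g' (dW^2 - dt)``.
    - ``heun_stratonovich``: Stratonovich predictor–corrector (midpoint
      average of drift and diffusion at the Euler predictor).
    """
    y = np.asarray(y, dtype=float)
    dW = np.asarray(dW, dtype=float)
    f0 = np.asarray(system.f(t, y), dtype=float)
    g0 = np.asarray(system.g(t, y), dtype=float)

    if method == "euler_maruyama":
        if system.wiener_type == "multi":
            return y + f0 * dt + g0 @ dW
        return y + f0 * dt + g0 * dW
    if method == "milstein":
        if system.wiener_type == "multi":
            raise ParameterError(
                "milstein supports scalar noise only; multi-dimensional "
                "non-commutative noise is not implemented"
            )
        gp = _diffusion_derivative(system.g, t, y)
        return y + f0 * dt + g0 * dW + 0.5 * g0 * gp * (dW * dW - dt)
    if method == "heun_stratonovich":
        if system.wiener_type == "multi":
            y_pred = y + f0 * dt + g0 @ dW
            f1 = np.asarray(system.f(t + dt, y_pred), dtype=float)
            g1 = np.asarray(system.g(t + dt, y_pred), dtype=float)
            return y + 0.5 * (f0 + f1) * dt + 0.5 * (g0 + g1) @ dW
        y_pred = y + f0 * dt + g0 * dW
        f1 = np.asarray(system.f(t + dt, y_pred), dtype=float)
        g1 = np.asarray(system.g(t + dt, y_pred), dtype=float)
        return y + 0.5 * (f0 + f1) * dt + 0.5 * (g0 + g1) * dW
    raise ParameterError(f"unknown SDE method {method!r}")
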