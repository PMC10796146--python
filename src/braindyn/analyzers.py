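"""Automatic dynamics analysis.

Three layers of machinery:

* 2-D phase planes: nullclines by sign-change scanning with 1-D root
  polishing, fixed points by multi-start root solving from candidate grid
  cells, stability from finite-difference Jacobian eigenvalues;
* grid-based bifurcation scans (one or two parameters) reusing the
  phase-plane machinery per grid point and reporting stability-change
  locations at grid resolution;
* high-dimensional slow-point search: minimize ``q(x) = 0.5 ||F(x)||^2``
  from many seeds, accept minima with ``||F||_inf <= tol``, merge
  near-duplicates, and characterize each point by the spectrum of the
  linearized dynamics.

Stability labels use a margin on the largest eigenvalue real part:
``|Re lambda| <= margin`` is reported as "marginal", which is what makes
line attractors (continua of neutrally stable points) visible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .errors import ParameterError

__all__ = [
    "FixedPoint",
    "PhasePlaneResult",
    "BifurcationResult",
    "numeric_jacobian",
    "linearize",
    "stability_label",
    "phase_plane_2d",
    "bifurcation_scan",
    "find_slow_points",
]

STABILITY_MARGIN = 1e-3


@dataclass
class FixedPoint:
    """An accepted equilibrium with its local linearization."""

    x: np.ndarray
    q: float
    eigenvalues: np.ndarray
    label: str
    jacobian: np.ndarray | None = None

    @property
    def residual_inf(self) -> float:
        return float(np.sqrt(2.0 * self.q / max(len(np.atleast_1d(self.x)), 1)))


@dataclass
class PhasePlaneResult:
    """Nullclines, vector field grid, and fixed points of a 2-D system."""

    nullclines: dict
    grid: tuple
    vector_field: tuple
    fixed_points: list
    diagnostics: str = ""


@dataclass
class BifurcationResult:
    """Fixed-point branches over a parameter grid plus stability changes."""

    param_names: tuple
    param_grid: list
    points: list  # list of (param values tuple, list[FixedPoint])
    stability_changes: list  # list of (param bracket, description)


def stability_label(eigenvalues, margin: float = STABILITY_MARGIN) -> str:
    """stable / unstable / saddle / marginal from eigenvalue real parts."""
    re = np.real(np.asarray(eigenvalues))
    if np.max(np.abs(re)) <= margin:
        return "marginal"
    if np.max(re) < -margin:
        return "stable"
    if np.min(re) > margin:
        return "unstable"
    if np.min(re) < -margin and np.max(re) > margin:
        return "saddle"
    # remaining case: some eigenvalues inside the margin band
    return "marginal" if np.max(re) <= margin else "unstable"


def numeric_jacobian(F, x, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-coordinate steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    F0 = np.atleast_1d(np.asarray(F(x), dtype=float))
    J = np.empty((F0.size, n))
    for i in range(n):
        h = rel_step * (1.0 + abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.atleast_1d(F(xp)) - np.atleast_1d(F(xm))) / (2.0 * h)
    return J


def linearize(F, x_star, margin: float = STABILITY_MARGIN):
    """Jacobian, eigenvalues, eigenvectors, and stability label at a point."""
    J = numeric_jacobian(F, x_star)
    eigvals, eigvecs = np.linalg.eig(J)
    return J, eigvals, eigvecs, stability_label(eigvals, margin)


def _dedupe(points: list, radius: float) -> list:
    """Merge points closer than ``radius``, keeping the lowest q."""
    kept: list = []
    for pt in sorted(points, key=lambda p: p.q):
        if all(np.linalg.norm(pt.x - other.x) > radius for other in kept):
            kept.append(pt)
    return kept


def _scan_nullcline(g, xs, ys, along_x: bool):
    """Zeros of g along grid lines by sign change + Brent polishing."""
    pts = []
    outer, inner = (ys, xs) if along_x else (xs, ys)
    for fixed in outer:
        if along_x:
            vals = np.array([g(x, fixed) for x in inner])
        else:
            vals = np.array([g(fixed, y) for y in inner])
        sign = np.sign(vals)
        for i in np.flatnonzero(np.diff(sign) != 0):
            a, b = inner[i], inner[i + 1]
            if vals[i] == 0.0:
                root = a
            else:
                try:
                    if along_x:
                        root = scipy.optimize.brentq(lambda x: g(x, fixed), a, b)
                    else:
                        root = scipy.optimize.brentq(lambda y: g(fixed, y), a, b)
                except ValueError:
                    continue
            pts.append((root, fixed) if along_x else (fixed, root))
    return np.asarray(pts) if pts else np.empty((0, 2))


def phase_plane_2d(f, x_range, y_range, resolution: int = 50,
                   tol: float = 1e-8, dedupe_radius: float = 1e-4,
                   margin: float = STABILITY_MARGIN) -> PhasePlaneResult:
    """Phase-plane analysis of ``f(x, y) -> (dx, dy)`` on a box.

    Fixed-point candidates are grid cells where both derivative components
    change sign nearby; each candidate seeds a 2-D root solve, solutions are
    deduplicated and classified by their Jacobian eigenvalues.  Finding no
    candidate returns an empty result with a diagnostic rather than raising.
    """
    xs = np.linspace(*x_range, resolution)
    ys = np.linspace(*y_range, resolution)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    DX = np.empty_like(XX)
    DY = np.empty_like(YY)
    for i, j in itertools.product(range(resolution), range(resolution)):
        dx, dy = f(XX[i, j], YY[i, j])
        DX[i, j], DY[i, j] = dx, dy

    null_x = _scan_nullcline(lambda x, y: f(x, y)[0], xs, ys, along_x=True)
    null_y = _scan_nullcline(lambda x, y: f(x, y)[1], xs, ys, along_x=False)

    # candidate cells: both components change sign within a 2x2 neighborhood
    seeds = []
    sx, sy = np.sign(DX), np.sign(DY)
    for i, j in itertools.product(range(resolution - 1), range(resolution - 1)):
        cx = sx[i:i + 2, j:j + 2]
        cy = sy[i:i + 2, j:j + 2]
        if cx.min() != cx.max() and cy.min() != cy.max():
            seeds.append((XX[i, j] + XX[i + 1, j], YY[i, j] + YY[i, j + 1]))
    seeds = [(0.5 * a, 0.5 * b) for a, b in seeds]

    def vec(z):
        dx, dy = f(z[0], z[1])
        return np.array([dx, dy], dtype=float)

    points = []
    for seed in seeds:
        sol = scipy.optimize.root(vec, np.asarray(seed, dtype=float),
                                  method="hybr", tol=tol * 1e-2)
        r = vec(sol.x)
        if np.max(np.abs(r)) <= max(tol, 1e-9):
            J, eigvals, _, label = linearize(vec, sol.x, margin)
            points.append(FixedPoint(x=sol.x.copy(), q=0.5 * float(r @ r),
                                     eigenvalues=eigvals, label=label, jacobian=J))
    points = [
        p for p in _dedupe(points, dedupe_radius)
        if x_range[0] - 1e-9 <= p.x[0] <= x_range[1] + 1e-9
        and y_range[0] - 1e-9 <= p.x[1] <= y_range[1] + 1e-9
    ]
    diag = "" if seeds else "no fixed-point candidates found on the grid"
    return PhasePlaneResult(
        nullclines={"dx=0": null_x, "dy=0": null_y},
        grid=(xs, ys),
        vector_field=(DX, DY),
        fixed_points=points,
        diagnostics=diag,
    )


def bifurcation_scan(f_of_params, param_grid: dict, x_range, y_range,
                     resolution: int = 40, tol: float = 1e-8,
                     margin: float = STABILITY_MARGIN) -> BifurcationResult:
    """Fixed points and stability across a 1-D or 2-D parameter grid.

    ``f_of_params(**params)`` must return a 2-D right-hand side
    ``f(x, y) -> (dx, dy)``.  Stability changes are reported as brackets
    ``((params_left, params_right), description)`` wherever the set of
    stability labels of the linked branch changes between adjacent grid
    points along the first parameter axis.
    """
    names = tuple(param_grid)
    if not (1 <= len(names) <= 2):
        raise ParameterError("bifurcation scans support one or two parameters")
    axes = [np.asarray(param_grid[n], dtype=float) for n in names]
    combos = list(itertools.product(*axes))

    points = []
    for combo in combos:
        f = f_of_params(**dict(zip(names, combo)))
        res = phase_plane_2d(f, x_range, y_range, resolution=resolution,
                             tol=tol, margin=margin)
        points.append((combo, res.fixed_points))

    changes = []
    # stability changes along the first axis (per value of the second axis)
    n0 = len(axes[0])
    n1 = len(axes[1]) if len(axes) > 1 else 1
    for j in range(n1):
        prev = None
        for i in range(n0):
            idx = i * n1 + j
            combo, fps = points[idx]
            labels = tuple(sorted(fp.label for fp in fps))
            if prev is not None and labels != prev[1]:
                changes.append(((prev[0], combo), f"{prev[1]} -> {labels}"))
            prev = (combo, labels)
    return BifurcationResult(param_names=names, param_grid=combos,
                             points=points, stability_changes=changes)


def _minimize_q(F, x0, method: str, max_iter: int, tol: float):
    """Drive ||F|| toward zero from one seed; returns the candidate point."""
    x0 = np.asarray(x0, dtype=float)
    if method == "least_squares":
        sol = scipy.optimize.least_squares(
            lambda x: np.asarray(F(x), dtype=float), x0,
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_iter,
        )
        return sol.x
    if method == "gd":
        x = x0.copy()
        step = 1.0
        for _ in range(max_iter):
            Fx = np.asarray(F(x), dtype=float)
            if np.max(np.abs(Fx)) <= tol:
                break
            J = numeric_jacobian(F, x)
            grad = J.T @ Fx
            gnorm = np.linalg.norm(grad)
            if gnorm == 0.0:
                break
            q0 = 0.5 * float(Fx @ Fx)
            step = min(step * 2.0, 1e3)
            while step > 1e-14:
                x_try = x - step * grad
                F_try = np.asarray(F(x_try), dtype=float)
                if 0.5 * float(F_try @ F_try) < q0 - 1e-4 * step * gnorm ** 2:
                    break
                step *= 0.5
            else:
                break
            x = x - step * grad
        return x
    raise ParameterError(f"unknown slow-point optimizer {method!r}")


def find_slow_points(F, seeds, tol: float = 1e-6, dedupe_radius: float | None = None,
                     method: str = "least_squares", max_iter: int = 2000,
                     margin: float = STABILITY_MARGIN) -> list:
    """Locate slow/fixed points of a high-dimensional flow ``F(x)``.

    Minimizes ``q(x) = 0.5 ||F(x)||^2`` from every seed (trust-region
    nonlinear least squares by default; plain gradient descent with
    backtracking via ``method="gd"``), keeps minima with
    ``||F(x)||_inf <= tol``, merges points closer than ``dedupe_radius``
    (default ``0.01 sqrt(dim)``) keeping the lowest q, and attaches the
    linearization.  Returns possibly-empty list sorted by q.
    """
    seeds = [np.asarray(s, dtype=float) for s in seeds]
    if not seeds:
        return []
    dim = seeds[0].size
    if dedupe_radius is None:
        dedupe_radius = 0.01 * np.sqrt(dim)

    accepted = []
    for s in seeds:
        if not np.all(np.isfinite(s)):
            continue
        x = _minimize_q(F, s, method, max_iter, tol)
        Fx = np.asarray(F(x), dtype=float)
        if not np.all(np.isfinite(Fx)):
            continue
        if np.max(np.abs(Fx)) <= tol:
            accepted.append(
                FixedPoint(x=x, q=0.5 * float(Fx @ Fx),
                           eigenvalues=np.empty(0), label="")
            )
    merged = _dedupe(accepted, dedupe_radius)
    for pt in merged:
        J, eigvals, _, label = linearize(F, pt.x, margin)
        pt.jacobian = J
        pt.eigenvalues = eigvals
        pt.label = label
    return sorted(merged, key=lambda p: p.q)
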