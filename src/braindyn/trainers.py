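"""Offline (ridge) and online (FORCE / recursive least squares) training of
linear readouts on echo-state reservoirs.

The reservoir is a leaky-tanh recurrence
``x_{t+1} = (1 - leak) x_t + leak tanh(W_rec x_t + W_in u_t)`` whose sparse
recurrent matrix is rescaled to a prescribed spectral radius; with radius
below 1 the state forgets its initial condition under a common input drive
(the echo-state property), which is what makes a fixed random reservoir a
usable feature map.  Readouts are linear and trained either in closed form
(ridge regression) or online by recursive least squares with an
inverse-correlation matrix (FORCE learning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .errors import ParameterError
from .fixtures import LorenzSpec, lorenz_series

__all__ = [
    "ReservoirParams",
    "build_reservoir_matrices",
    "reservoir_collect",
    "RidgeSpec",
    "ridge_fit",
    "RLSState",
    "init_rls",
    "force_step",
    "force_train",
    "train_and_forecast",
]


@dataclass(frozen=True)
class ReservoirParams:
    """Echo-state reservoir hyperparameters."""

    N: int = 400
    spectral_radius: float = 0.9
    input_scale: float = 0.1
    leak_rate: float = 1.0
    density: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.leak_rate <= 1.0):
            raise ParameterError("leak rate must be in (0, 1]")
        if not (0.0 <= self.density <= 1.0):
            raise ParameterError("density must be in [0, 1]")


def build_reservoir_matrices(params: ReservoirParams, d_in: int):
    """Random sparse recurrent matrix (rescaled to the requested spectral
    radius within 1e-6) and dense input matrix, deterministic per seed."""
    rng = np.random.default_rng(params.seed)
    W = scipy.sparse.random(
        params.N, params.N, density=params.density, random_state=rng,
        data_rvs=rng.standard_normal, format="csr",
    )
    if W.nnz == 0:
        raise ParameterError(
            "recurrent matrix has no entries; cannot rescale an all-zero matrix"
        )
    if params.N > 2:
        lam = scipy.sparse.linalg.eigs(W, k=1, which="LM",
                                       return_eigenvectors=False, tol=1e-9)
        radius = float(np.abs(lam[0]))
    else:
        radius = float(np.max(np.abs(np.linalg.eigvals(W.toarray()))))
    if radius == 0.0:
        raise ParameterError("recurrent matrix is nilpotent; cannot set spectral radius")
    W = W * (params.spectral_radius / radius)
    W_in = params.input_scale * rng.uniform(-1.0, 1.0, size=(params.N, d_in))
    return W, W_in


def reservoir_collect(params: ReservoirParams, inputs: np.ndarray,
                      x0: np.ndarray | None = None) -> np.ndarray:
    """Run the leaky-tanh recursion over ``inputs [T x d_in]``; returns states
    ``[T x N]`` (state after consuming each input row)."""
    U = np.asarray(inputs, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if not np.all(np.isfinite(U)):
        raise ParameterError("inputs must be finite")
    W, W_in = build_reservoir_matrices(params, U.shape[1])
    x = np.zeros(params.N) if x0 is None else np.asarray(x0, dtype=float).copy()
    leak = params.leak_rate
    X = np.empty((U.shape[0], params.N))
    for t in range(U.shape[0]):
        x = (1.0 - leak) * x + leak * np.tanh(W @ x + W_in @ U[t])
        X[t] = x
    return X


@dataclass(frozen=True)
class RidgeSpec:
    """Ridge regularization strength."""

    lam: float = 1e-6

    def __post_init__(self):
        if self.lam < 0:
            raise ParameterError("regularization must be nonnegative")


def ridge_fit(states: np.ndarray, targets: np.ndarray,
              spec: RidgeSpec = RidgeSpec()) -> np.ndarray:
    """Closed-form readout ``W = (X'X + lam I)^-1 X'Y``.

    Solved through a symmetric positive-definite factorization; at
    ``lam = 0`` a singular normal system falls back to the least-norm
    solution with a rank warning.
    """
    X = np.atleast_2d(np.asarray(states, dtype=float))
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    G = X.T @ X
    rhs = X.T @ Y
    if spec.lam == 0.0:
        rank = np.linalg.matrix_rank(G)
        if rank < G.shape[0]:
            warnings.warn(
                "normal equations singular at lam=0; returning the least-norm "
                "solution", RuntimeWarning, stacklevel=2,
            )
            return np.linalg.lstsq(X, Y, rcond=None)[0]
        return scipy.linalg.solve(G, rhs, assume_a="pos")
    G = G + spec.lam * np.eye(G.shape[0])
    return scipy.linalg.solve(G, rhs, assume_a="pos")


@dataclass
class RLSState:
    """Recursive-least-squares state: readout W and inverse correlation P."""

    W: np.ndarray
    P: np.ndarray


def init_rls(n_features: int, d_out: int, alpha: float = 1.0) -> RLSState:
    """Initialize FORCE learning with ``P0 = I / alpha`` (alpha acts like an
    effective ridge penalty) and a zero readout."""
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    return RLSState(
        W=np.zeros((n_features, d_out)),
        P=np.eye(n_features) / alpha,
    )


def force_step(rls: RLSState, x: np.ndarray, y_target: np.ndarray) -> RLSState:
    """One FORCE/RLS update on a single sample (in place; returns the state).

    ``k = P x / (1 + x' P x)``; error ``e = W' x - y``; ``W -= k e'``;
    ``P -= k (P x)'`` (rank-1 downdate keeping P symmetric positive
    definite).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.atleast_1d(np.asarray(y_target, dtype=float))
    Px = rls.P @ x
    denom = 1.0 + float(x @ Px)
    k = Px / denom
    e = rls.W.T @ x - y
    rls.W -= np.outer(k, e)
    rls.P -= np.outer(k, Px)
    # numerical symmetrization guards the SPD invariant over long runs
    rls.P = 0.5 * (rls.P + rls.P.T)
    if not (np.all(np.isfinite(rls.W)) and np.all(np.isfinite(rls.P))):
        raise ParameterError("FORCE update diverged to non-finite values")
    return rls


def force_train(states: np.ndarray, targets: np.ndarray, alpha: float = 1.0,
                n_passes: int = 1) -> np.ndarray:
    """Sequential FORCE/RLS pass(es) over a batch; returns the readout."""
    X = np.asarray(states, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rls = init_rls(X.shape[1], Y.shape[1], alpha=alpha)
    for _ in range(n_passes):
        for x, y in zip(X, Y):
            force_step(rls, x, y)
    return rls.W


@dataclass(frozen=True)
class SplitSpec:
    """Washout/train/test proportions of the series (in that order)."""

    washout: float = 0.1
    train: float = 0.7

    def __post_init__(self):
        if not (0.0 <= self.washout < 1.0 and 0.0 < self.train < 1.0
                and self.washout + self.train < 1.0):
            raise ParameterError("invalid split proportions")


def train_and_forecast(
    task: str = "lorenz_prediction",
    method: str = "ridge",
    params: ReservoirParams = ReservoirParams(),
    split: SplitSpec = SplitSpec(),
    lam: float = 1e-6,
    alpha: float = 1.0,
    lorenz: LorenzSpec | None = None,
    include_bias: bool = True,
):
    """Teacher-forced one-step prediction of a chaotic Lorenz series.

    The series is standardized per variable with training-split statistics;
    the readout maps the reservoir state at time ``t`` (plus a bias feature)
    to the series value at ``t+1``.  Returns ``(weights, test_mse, info)``
    with the MSE averaged over variables and test steps on the standardized
    scale.
    """
    if task != "lorenz_prediction":
        raise ParameterError(f"unknown task {task!r}")
    if method not in ("ridge", "force"):
        raise ParameterError(f"unknown training method {method!r}")
    spec = lorenz or LorenzSpec()
    series = lorenz_series(spec)
    T = len(series)
    n_wash = int(T * split.washout)
    n_train_end = n_wash + int(T * split.train)

    mean = series[n_wash:n_train_end].mean(axis=0)
    std = series[n_wash:n_train_end].std(axis=0)
    Z = (series - mean) / std

    U = Z[:-1]
    Y = Z[1:]
    X = reservoir_collect(params, U)
    if include_bias:
        X = np.hstack([X, np.ones((len(X), 1))])

    Xtr, Ytr = X[n_wash:n_train_end], Y[n_wash:n_train_end]
    Xte, Yte = X[n_train_end:], Y[n_train_end:]

    if method == "ridge":
        W = ridge_fit(Xtr, Ytr, RidgeSpec(lam=lam))
    else:
        W = force_train(Xtr, Ytr, alpha=alpha, n_passes=1)

    pred_tr = Xtr @ W
    pred_te = Xte @ W
    train_mse = float(np.mean((pred_tr - Ytr) ** 2))
    test_mse = float(np.mean((pred_te - Yte) ** 2))
    info = {
        "task": task,
        "method": method,
        "reservoir": params,
        "split": split,
        "lam": lam,
        "alpha": alpha,
        "lorenz": spec,
        "train_mse": train_mse,
        "n_train": len(Xtr),
        "n_test": len(Xte),
        "standardization": {"mean": mean.tolist(), "std": std.tolist()},
    }
    return W, test_mse, info
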