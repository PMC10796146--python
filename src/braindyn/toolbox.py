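"""Connectivity builders, weight initializers, stimulus constructors, and
basic activity measures.

Random connectivity uses the same per-row counter-based stream as the
matrix-free operators in :mod:`braindyn.sparse`, so a stored connector and a
matrix-free operator built from the same seed realize identical connectivity.
Neuron indexing is 0-based everywhere.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .sparse import CSRMatrix, bernoulli_row_indices, row_stream

__all__ = [
    "fixed_prob_conn",
    "all2all_conn",
    "one2one_conn",
    "ring_gaussian_weights",
    "build_connectivity",
    "section_input",
    "poisson_spikes",
    "firing_rate",
    "init_constant",
    "init_uniform",
    "init_normal",
]


def fixed_prob_conn(
    n_pre: int,
    n_post: int,
    p: float,
    seed: int,
    include_self: bool = True,
    weight: float = 1.0,
) -> CSRMatrix:
    """Independent Bernoulli(p) connectivity with sorted column indices.

    With ``include_self=False`` and a square shape, self-pairs ``i -> i`` are
    excluded.  Row ``i`` is drawn from the stream keyed by ``(seed, i)``; with
    ``include_self=True`` the realization equals
    ``materialize_jitconn(JitConnSpec(p, seed, (n_pre, n_post), weight))``.
    """
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"connection probability must be in [0, 1], got {p}")
    cols_per_row = []
    counts = np.zeros(n_pre, dtype=np.int64)
    square = n_pre == n_post
    for i in range(n_pre):
        cols = bernoulli_row_indices(row_stream(seed, i), n_post, p)
        if not include_self and square:
            cols = cols[cols != i]
        cols_per_row.append(cols)
        counts[i] = cols.size
    indptr = np.concatenate([[0], np.cumsum(counts)])
    indices = (
        np.concatenate(cols_per_row) if cols_per_row else np.empty(0, dtype=np.int64)
    )
    return CSRMatrix(data=float(weight), indices=indices, indptr=indptr,
                     shape=(n_pre, n_post))


def all2all_conn(n_pre: int, n_post: int, include_self: bool = True,
                 weight: float = 1.0) -> CSRMatrix:
    """Dense connectivity in CSR form."""
    rows = []
    for i in range(n_pre):
        cols = np.arange(n_post, dtype=np.int64)
        if not include_self and n_pre == n_post:
            cols = cols[cols != i]
        rows.append(cols)
    counts = np.array([r.size for r in rows], dtype=np.int64)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return CSRMatrix(data=float(weight), indices=np.concatenate(rows),
                     indptr=indptr, shape=(n_pre, n_post))


def one2one_conn(n: int, weight: float = 1.0) -> CSRMatrix:
    return CSRMatrix(
        data=float(weight),
        indices=np.arange(n, dtype=np.int64),
        indptr=np.arange(n + 1, dtype=np.int64),
        shape=(n, n),
    )


def ring_gaussian_weights(n: int, J0: float, a: float, L: float = 2 * np.pi) -> np.ndarray:
    """Translation-invariant Gaussian coupling on a ring of circumference L.

    ``w[i, j] = J0/(sqrt(2 pi) a) * exp(-d(x_i, x_j)^2 / (2 a^2))`` with ``d``
    the circular distance between the evenly spaced positions ``x_i``.
    """
    if n < 3:
        raise ParameterError("ring needs at least 3 nodes")
    if a <= 0:
        raise ParameterError("kernel width a must be positive")
    x = np.arange(n) * (L / n)
    diff = np.abs(x[:, None] - x[None, :])
    d = np.minimum(diff, L - diff)
    return J0 / (np.sqrt(2 * np.pi) * a) * np.exp(-(d ** 2) / (2 * a ** 2))


def build_connectivity(spec: dict) -> CSRMatrix | np.ndarray:
    """Build connectivity from a config-style dict (``kind`` + parameters)."""
    kind = spec.get("kind")
    if kind == "fixed_prob":
        return fixed_prob_conn(
            spec["n_pre"], spec["n_post"], spec["p"], spec["seed"],
            include_self=spec.get("include_self", True),
            weight=spec.get("weight", 1.0),
        )
    if kind == "all2all":
        return all2all_conn(spec["n_pre"], spec["n_post"],
                            include_self=spec.get("include_self", True),
                            weight=spec.get("weight", 1.0))
    if kind == "one2one":
        return one2one_conn(spec["n"], weight=spec.get("weight", 1.0))
    if kind == "ring_gaussian":
        return ring_gaussian_weights(spec["n"], spec["J0"], spec["a"],
                                     L=spec.get("L", 2 * np.pi))
    raise ParameterError(f"unknown connectivity kind {kind!r}")


def section_input(segments, dt: float) -> np.ndarray:
    """Concatenate constant segments ``(value, duration_ms)`` at resolution dt.

    An empty program yields an empty array.  Each segment contributes
    ``round(duration/dt)`` samples.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    chunks = []
    for value, duration in segments:
        if duration <= 0:
            raise ParameterError("segment durations must be positive")
        n = int(round(duration / dt))
        chunks.append(np.full(n, float(value)))
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def poisson_spikes(rate: float, n_channels: int, duration: float, dt: float,
                   seed: int) -> np.ndarray:
    """Independent Bernoulli spike raster approximating Poisson processes.

    Per-bin spike probability is ``rate * dt / 1000`` (rate in Hz, dt in ms);
    it must stay below 1.
    """
    p = rate * dt / 1000.0
    if p < 0 or p >= 1:
        raise ParameterError(f"per-bin probability {p} must lie in [0, 1)")
    steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    return rng.random((steps, n_channels)) < p


def firing_rate(spikes: np.ndarray, window: float, dt: float) -> np.ndarray:
    """Population firing rate in Hz from a boolean raster [steps x n].

    A centered moving window of ``window`` ms counts spikes across the
    population; the count is divided by ``n * window`` and rescaled to Hz.
    """
    if window < dt:
        raise ParameterError("window must be at least one time step")
    spikes = np.asarray(spikes, dtype=bool)
    steps, n = spikes.shape
    wsteps = max(1, int(round(window / dt)))
    counts = spikes.sum(axis=1).astype(np.float64)
    kernel = np.ones(wsteps)
    summed = np.convolve(counts, kernel, mode="same")
    return summed / (n * wsteps * dt) * 1000.0


def init_constant(shape, value: float) -> np.ndarray:
    return np.full(shape, float(value))


def init_uniform(shape, low: float, high: float, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).uniform(low, high, size=shape)


def init_normal(shape, mean: float, sigma: float, seed: int) -> np.ndarray:
    return mean + sigma * np.random.default_rng(seed).standard_normal(shape)
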