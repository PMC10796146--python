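"""Sparse and event-driven synaptic operators.

Connectivity is stored row-compressed with **rows = presynaptic neurons**.
The event-driven matrix–vector product touches only the rows whose neuron
spiked this step, which is what makes synaptic computation cost proportional
to activity rather than to the full connectivity size.

Matrix-free ("just-in-time connectivity") variants regenerate random
connectivity deterministically from a seed at every call instead of storing
it.  The random stream is fixed bit-exactly so a matrix-free call and a
materialized matrix built from the same spec agree entry for entry:

* row ``i`` of a spec with seed ``s`` uses the generator
  ``numpy PCG64(SeedSequence(entropy=s, spawn_key=(i,)))``;
* column indices are drawn by geometric skip sampling of Bernoulli(p):
  repeatedly advance ``j += 1 + floor(log(1-u)/log(1-p))`` with uniforms
  ``u`` from the row stream, collecting every ``j < n_post``;
* if weights are normal(mu, sigma), one normal variate per realized edge is
  drawn from the *same* row stream, after all of the row's indices.

All accumulations run in float64 regardless of input precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .errors import ParameterError, ShapeError

__all__ = [
    "CSRMatrix",
    "EventVector",
    "JitConnSpec",
    "csr_matvec",
    "event_csr_matvec",
    "jitconn_event_matvec",
    "materialize_jitconn",
    "syn2post_sum",
    "pre2syn_gather",
    "row_stream",
    "bernoulli_row_indices",
]


@dataclass
class CSRMatrix:
    """Row-compressed connectivity: rows presynaptic, columns postsynaptic.

    ``data`` is either a per-edge float64 array of length ``nnz`` or a scalar
    for homogeneous weights.
    """

    data: np.ndarray | float
    indices: np.ndarray
    indptr: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        n_pre, n_post = self.shape
        if len(self.indptr) != n_pre + 1:
            raise ShapeError("indptr length must be n_pre + 1")
        if np.any(np.diff(self.indptr) < 0):
            raise ShapeError("indptr must be nondecreasing")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= n_post
        ):
            raise ShapeError("column indices out of range")
        if not np.isscalar(self.data):
            self.data = np.asarray(self.data, dtype=np.float64)
            if self.data.shape != self.indices.shape:
                raise ShapeError("data length must equal nnz (or be scalar)")

    @property
    def nnz(self) -> int:
        return int(self.indices.size)

    @property
    def homogeneous(self) -> bool:
        return np.isscalar(self.data)

    def edge_weights(self) -> np.ndarray:
        """Per-edge weights as a float64 array (scalar broadcast if needed)."""
        if self.homogeneous:
            return np.full(self.nnz, float(self.data))
        return self.data

    def row_ids(self) -> np.ndarray:
        """Presynaptic id of every edge, aligned with ``indices``."""
        return np.repeat(
            np.arange(self.shape[0], dtype=np.int64), np.diff(self.indptr)
        )

    # -- conversions ------------------------------------------------------

    def to_scipy(self) -> scipy.sparse.csr_matrix:
        return scipy.sparse.csr_matrix(
            (self.edge_weights(), self.indices.copy(), self.indptr.copy()),
            shape=self.shape,
        )

    @classmethod
    def from_scipy(cls, m) -> "CSRMatrix":
        m = scipy.sparse.csr_matrix(m)
        m.sort_indices()
        return cls(
            data=np.asarray(m.data, dtype=np.float64),
            indices=m.indices,
            indptr=m.indptr,
            shape=m.shape,
        )

    @classmethod
    def from_dense(cls, dense) -> "CSRMatrix":
        return cls.from_scipy(scipy.sparse.csr_matrix(np.asarray(dense, dtype=float)))

    def to_dense(self) -> np.ndarray:
        return self.to_scipy().toarray()

    def to_mtx(self, path) -> None:
        scipy.io.mmwrite(str(path), self.to_scipy())

    @classmethod
    def from_mtx(cls, path) -> "CSRMatrix":
        return cls.from_scipy(scipy.io.mmread(str(path)))

    @classmethod
    def from_edges(cls, pre_ids, post_ids, weights, shape) -> "CSRMatrix":
        """Build from an edge list; duplicate edges are kept (operators sum them)."""
        pre_ids = np.asarray(pre_ids, dtype=np.int64)
        post_ids = np.asarray(post_ids, dtype=np.int64)
        w = np.broadcast_to(np.asarray(weights, dtype=np.float64), pre_ids.shape)
        order = np.lexsort((post_ids, pre_ids))
        counts = np.bincount(pre_ids, minlength=shape[0])
        indptr = np.concatenate([[0], np.cumsum(counts)])
        return cls(
            data=w[order].copy(), indices=post_ids[order], indptr=indptr, shape=shape
        )


@dataclass
class EventVector:
    """Boolean spike vector (True = the neuron spiked this step)."""

    events: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events)
        if self.events.dtype != np.bool_:
            raise ParameterError("events must be boolean")

    def __len__(self):
        return len(self.events)


def _as_events(e) -> np.ndarray:
    arr = e.events if isinstance(e, EventVector) else np.asarray(e)
    if arr.dtype != np.bool_:
        raise ParameterError("events must be boolean")
    return arr


def csr_matvec(m: CSRMatrix, v, transpose: bool = False) -> np.ndarray:
    """Sparse matrix–vector product ``m @ v`` (or ``m.T @ v``).

    ``transpose=True`` computes the transpose product by scattering, without
    materializing the transposed matrix.
    """
    v = np.asarray(v, dtype=np.float64)
    n_pre, n_post = m.shape
    if transpose:
        if v.shape != (n_pre,):
            raise ShapeError(f"expected vector of length {n_pre}, got {v.shape}")
        contrib = m.edge_weights() * v[m.row_ids()]
        return np.bincount(m.indices, weights=contrib, minlength=n_post)
    if v.shape != (n_post,):
        raise ShapeError(f"expected vector of length {n_post}, got {v.shape}")
    contrib = m.edge_weights() * v[m.indices]
    return np.bincount(m.row_ids(), weights=contrib, minlength=n_pre)


def event_csr_matvec(m: CSRMatrix, e, transpose: bool = False) -> np.ndarray:
    """Event-driven product over a boolean spike vector.

    Default direction is presynaptic events to postsynaptic sums:
    ``out[j] = sum over spiking presynaptic i of weight(i -> j)`` (the
    transpose product ``m.T @ e`` in matrix terms), iterating only over rows
    with events.  ``transpose=True`` flips the direction: ``e`` indexes
    postsynaptic neurons and ``out[i]`` sums the weights of row ``i``'s
    active targets.
    """
    ev = _as_events(e)
    n_pre, n_post = m.shape
    if transpose:
        if ev.shape != (n_post,):
            raise ShapeError(f"expected events of length {n_post}, got {ev.shape}")
        contrib = m.edge_weights() * ev[m.indices]
        return np.bincount(m.row_ids(), weights=contrib, minlength=n_pre)
    if ev.shape != (n_pre,):
        raise ShapeError(f"expected events of length {n_pre}, got {ev.shape}")
    active = np.flatnonzero(ev)
    out = np.zeros(n_post, dtype=np.float64)
    if active.size == 0:
        return out
    starts = m.indptr[active]
    stops = m.indptr[active + 1]
    lengths = stops - starts
    # gather the column slices of active rows only
    pos = np.repeat(starts - np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths)
    idx = pos + np.arange(int(lengths.sum()), dtype=np.int64)
    cols = m.indices[idx]
    if m.homogeneous:
        counts = np.bincount(cols, minlength=n_post)
        return float(m.data) * counts.astype(np.float64)
    np.add.at(out, cols, m.data[idx])
    return out


@dataclass(frozen=True)
class JitConnSpec:
    """Matrix-free random connectivity: a pure function of its fields.

    ``weight`` is either a scalar (homogeneous) or a ``(mu, sigma)`` pair for
    per-edge normal weights.
    """

    prob: float
    seed: int
    shape: tuple[int, int]
    weight: float | tuple[float, float] = 1.0

    def __post_init__(self):
        if not (0.0 <= self.prob <= 1.0):
            raise ParameterError(f"connection probability must be in [0, 1], got {self.prob}")


def row_stream(seed: int, row: int) -> np.random.Generator:
    """The documented per-row random stream: PCG64 keyed by (seed, row)."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(row,)))
    )


def bernoulli_row_indices(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Sorted indices of Bernoulli(p) successes among ``0..n-1``.

    Uses geometric skip sampling: consecutive gaps are geometric variates
    derived from single uniforms, so the cost is proportional to the number
    of realized connections.
    """
    if p <= 0.0 or n == 0:
        return np.empty(0, dtype=np.int64)
    if p >= 1.0:
        return np.arange(n, dtype=np.int64)
    log_q = np.log1p(-p)
    out = []
    j = -1
    while True:
        u = rng.random()
        j += 1 + int(np.log1p(-u) / log_q)
        if j >= n:
            break
        out.append(j)
    return np.asarray(out, dtype=np.int64)


def _jit_row(spec: JitConnSpec, row: int):
    """(column indices, weights) of one row of the realized connectivity."""
    rng = row_stream(spec.seed, row)
    cols = bernoulli_row_indices(rng, spec.shape[1], spec.prob)
    if isinstance(spec.weight, tuple):
        mu, sigma = spec.weight
        w = mu + sigma * rng.standard_normal(cols.size)
    else:
        w = np.full(cols.size, float(spec.weight))
    return cols, w


def materialize_jitconn(spec: JitConnSpec) -> CSRMatrix:
    """Realize the full CSR matrix a :class:`JitConnSpec` denotes."""
    n_pre, n_post = spec.shape
    all_cols, all_w, counts = [], [], np.zeros(n_pre, dtype=np.int64)
    for i in range(n_pre):
        cols, w = _jit_row(spec, i)
        all_cols.append(cols)
        all_w.append(w)
        counts[i] = cols.size
    indptr = np.concatenate([[0], np.cumsum(counts)])
    indices = np.concatenate(all_cols) if all_cols else np.empty(0, dtype=np.int64)
    data = np.concatenate(all_w) if all_w else np.empty(0)
    return CSRMatrix(data=data, indices=indices, indptr=indptr, shape=spec.shape)


def jitconn_event_matvec(spec: JitConnSpec, e, transpose: bool = False) -> np.ndarray:
    """Event-driven product against connectivity regenerated from the seed.

    Equals ``event_csr_matvec(materialize_jitconn(spec), e, transpose)``
    exactly, but stores no connectivity between calls.  In the default
    direction only the rows of spiking presynaptic neurons are regenerated.
    """
    ev = _as_events(e)
    n_pre, n_post = spec.shape
    if transpose:
        if ev.shape != (n_post,):
            raise ShapeError(f"expected events of length {n_post}, got {ev.shape}")
        out = np.zeros(n_pre, dtype=np.float64)
        for i in range(n_pre):
            cols, w = _jit_row(spec, i)
            if cols.size:
                # accumulate in the same sequential edge order as the
                # stored-matrix operator so the two agree bit for bit
                out[i] = np.bincount(np.zeros(cols.size, dtype=np.int64),
                                     weights=w * ev[cols], minlength=1)[0]
        return out
    if ev.shape != (n_pre,):
        raise ShapeError(f"expected events of length {n_pre}, got {ev.shape}")
    out = np.zeros(n_post, dtype=np.float64)
    for i in np.flatnonzero(ev):
        cols, w = _jit_row(spec, int(i))
        np.add.at(out, cols, w)
    return out


def syn2post_sum(syn_values, post_ids, n_post: int) -> np.ndarray:
    """Segment sum of per-edge values onto postsynaptic neurons."""
    syn_values = np.asarray(syn_values, dtype=np.float64)
    post_ids = np.asarray(post_ids, dtype=np.int64)
    if syn_values.shape != post_ids.shape:
        raise ShapeError("syn_values and post_ids must have equal length")
    if post_ids.size and (post_ids.min() < 0 or post_ids.max() >= n_post):
        raise IndexError("postsynaptic id out of range")
    return np.bincount(post_ids, weights=syn_values, minlength=n_post)


def pre2syn_gather(pre_values, pre_ids) -> np.ndarray:
    """Gather per-neuron values onto edges: ``out[k] = pre_values[pre_ids[k]]``."""
    pre_values = np.asarray(pre_values, dtype=np.float64)
    pre_ids = np.asarray(pre_ids, dtype=np.int64)
    if pre_ids.size and (pre_ids.min() < 0 or pre_ids.max() >= len(pre_values)):
        raise IndexError("presynaptic id out of range")
    return pre_values[pre_ids]
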