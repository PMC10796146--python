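"""Hierarchical composable dynamical systems and the fixed-step simulation runner.

A model is a tree of :class:`DynSystemNode` objects.  Every node owns named
state variables and parameters; composing nodes builds larger models whose
full state is the disjoint union of the states of all nodes in the tree,
addressed by dotted paths (``"INa.m"``, ``"net.neuron.V"``).  Within one time
step children update before their parent integrates its own states, in
insertion order, which fixes a deterministic, documented intra-step pipeline.

Simulation is fixed-step: :func:`run` advances the tree ``ceil(duration/dt)``
times, samples monitored variables at a configurable stride, and aborts with a
diagnostic on the first non-finite state.  Identical ``(model, inputs, seed)``
produce bit-identical records.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    CompositionError,
    DivergenceError,
    GridError,
    NamingError,
    ParameterError,
    PathError,
)

__all__ = [
    "StateVar",
    "DynSystemNode",
    "DelayBuffer",
    "MonitorSpec",
    "SimulationRecord",
    "compose",
    "run",
    "batch_run",
]


class StateVar:
    """A named numeric array with a role (state, parameter, or buffer).

    The shape is fixed at construction; ``reset`` restores the initial value.
    """

    __slots__ = ("name", "role", "value", "_initial")

    def __init__(self, name: str, value, role: str = "state"):
        if role not in ("state", "parameter", "buffer"):
            raise ParameterError(f"unknown StateVar role {role!r}")
        arr = np.asarray(value)
        if arr.dtype.kind not in "fbiu":
            raise ParameterError(f"state {name!r} must be numeric or boolean")
        if arr.dtype.kind == "f":
            arr = arr.astype(np.float64)
        self.name = name
        self.role = role
        self.value = arr.copy()
        self._initial = arr.copy()

    @property
    def shape(self):
        return self.value.shape

    def set(self, value) -> None:
        arr = np.asarray(value, dtype=self.value.dtype)
        if arr.shape != self.value.shape:
            raise ParameterError(
                f"state {self.name!r} has fixed shape {self.value.shape}, "
                f"got {arr.shape}"
            )
        self.value = arr

    def reset(self) -> None:
        self.value = self._initial.copy()

    def rebase(self) -> None:
        """Make the current value the new initial value."""
        self._initial = np.asarray(self.value).copy()

    def __repr__(self):
        return f"StateVar({self.name!r}, shape={self.value.shape}, role={self.role!r})"


class DynSystemNode:
    """A named dynamical component; composes into trees.

    Subclasses override :meth:`own_update` to advance their own states by one
    step given ``(t, dt, inputs)``.  :meth:`update` first updates all children
    (in insertion order) and then calls ``own_update``.
    """

    def __init__(self, name: str = "node", **params):
        self.name = name
        self.params: dict = dict(params)
        self.states: dict[str, StateVar] = {}
        self.children: dict[str, DynSystemNode] = {}
        self.parent: DynSystemNode | None = None
        self.rng: np.random.Generator = np.random.default_rng(0)

    # -- construction -----------------------------------------------------

    def add_state(self, name: str, value, role: str = "state") -> StateVar:
        if name in self.states:
            raise NamingError(f"duplicate state name {name!r} in node {self.name!r}")
        sv = StateVar(name, value, role)
        self.states[name] = sv
        return sv

    def add_child(self, child: "DynSystemNode", name: str | None = None) -> "DynSystemNode":
        return compose(self, child, name or child.name)

    # -- tree access ------------------------------------------------------

    def iter_nodes(self) -> Iterable["DynSystemNode"]:
        yield self
        for child in self.children.values():
            yield from child.iter_nodes()

    def state_items(self, prefix: str = "") -> Iterable[tuple[str, StateVar]]:
        """All (dotted path, StateVar) pairs of this subtree, own states first."""
        for name, sv in self.states.items():
            yield prefix + name, sv
        for cname, child in self.children.items():
            yield from child.state_items(prefix + cname + ".")

    def state_paths(self) -> list[str]:
        return [path for path, _ in self.state_items()]

    def find_state(self, path: str) -> StateVar:
        node = self
        parts = path.split(".")
        for part in parts[:-1]:
            if part not in node.children:
                raise PathError(f"no child {part!r} under node {node.name!r} "
                                f"while resolving {path!r}")
            node = node.children[part]
        leaf = parts[-1]
        if leaf not in node.states:
            raise PathError(f"no state {leaf!r} in node {node.name!r} "
                            f"while resolving {path!r}")
        return node.states[leaf]

    # -- dynamics ---------------------------------------------------------

    def update(self, t: float, dt: float, inputs: Mapping[str, np.ndarray]) -> None:
        for child in self.children.values():
            child.update(t, dt, inputs)
        self.own_update(t, dt, inputs)

    def own_update(self, t: float, dt: float, inputs: Mapping[str, np.ndarray]) -> None:
        """Advance this node's own states by one step.  Default: nothing."""

    def reset(self) -> None:
        for child in self.children.values():
            child.reset()
        for sv in self.states.values():
            sv.reset()
        self.reset_hook()

    def reset_hook(self) -> None:
        """Extra reset logic for subclasses (e.g. refilling delay buffers)."""

    def set_rng(self, rng: np.random.Generator) -> None:
        """Install a shared random generator on every node of the subtree."""
        for node in self.iter_nodes():
            node.rng = rng

    def describe(self) -> str:
        kids = ", ".join(self.children)
        return f"{type(self).__name__}({self.name!r}, children=[{kids}])"

    def __repr__(self):
        return self.describe()


def compose(parent: DynSystemNode, child: DynSystemNode, name: str) -> DynSystemNode:
    """Attach ``child`` to ``parent`` under ``name``; returns ``parent``.

    The composition graph must stay a tree: attaching an ancestor (or the
    node itself) raises :class:`CompositionError`, a duplicate child name
    raises :class:`NamingError`.
    """
    if name in parent.children:
        raise NamingError(f"node {parent.name!r} already has a child named {name!r}")
    node: DynSystemNode | None = parent
    while node is not None:
        if node is child:
            raise CompositionError(
                f"attaching {child.name!r} under {parent.name!r} would create a cycle"
            )
        node = node.parent
    if child.parent is not None:
        raise CompositionError(f"node {child.name!r} already has a parent")
    parent.children[name] = child
    child.parent = parent
    return parent


class DelayBuffer:
    """Ring buffer giving access to past values of a signal.

    Delays are rounded to the nearest integer step; before the history fills,
    reads return the declared initial value.
    """

    def __init__(self, max_delay: float, dt: float, initial_value):
        if dt <= 0:
            raise ParameterError("dt must be positive")
        if max_delay < 0:
            raise ParameterError("max delay must be nonnegative")
        self.dt = float(dt)
        self.max_steps = int(round(max_delay / dt))
        init = np.asarray(initial_value, dtype=float)
        self._initial = init.copy()
        self._hist = np.tile(init, (self.max_steps + 1,) + (1,) * init.ndim)
        self._pos = 0  # index of the current value

    def push(self, value) -> None:
        self._pos = (self._pos + 1) % (self.max_steps + 1)
        self._hist[self._pos] = np.asarray(value, dtype=float)

    def read(self, delay: float):
        """Value from ``round(delay/dt)`` steps in the past (0 = current)."""
        steps = int(round(delay / self.dt))
        if delay < 0 or steps > self.max_steps:
            raise ParameterError(
                f"delay {delay} outside buffer capacity {self.max_steps * self.dt}"
            )
        return self._hist[(self._pos - steps) % (self.max_steps + 1)].copy()

    def reset(self) -> None:
        self._hist[:] = self._initial
        self._pos = 0


@dataclass(frozen=True)
class MonitorSpec:
    """What to record: a dotted state path sampled every ``every_n_steps``."""

    target: str
    every_n_steps: int = 1

    def __post_init__(self):
        if self.every_n_steps < 1:
            raise ParameterError("every_n_steps must be a positive integer")


@dataclass
class SimulationRecord:
    """Time grid, monitored series, and run metadata of one simulation."""

    times: dict[str, np.ndarray]
    series: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def time(self, target: str) -> np.ndarray:
        return self.times[target]

    def __getitem__(self, target: str) -> np.ndarray:
        return self.series[target]


def _input_value(spec, step: int, t: float):
    if callable(spec):
        return spec(t, step)
    arr = np.asarray(spec)
    if arr.ndim == 0:
        return arr
    return arr[step]


def run(
    model: DynSystemNode,
    duration: float,
    dt: float,
    inputs: Mapping[str, object] | None = None,
    monitors: Sequence[MonitorSpec | str] = (),
    seed: int = 0,
    reset: bool = True,
) -> SimulationRecord:
    """Simulate ``model`` for ``duration`` ms at fixed step ``dt`` ms.

    ``inputs`` maps input names to scalars, per-step arrays, or callables
    ``(t, step) -> value``; the resolved values are passed to every node's
    update rule each step.  Monitors are sampled after the update, at times
    ``dt * every_n_steps * (1, 2, ...)``.

    Identical ``(model, inputs, seed)`` give bit-identical records.  The
    first non-finite state aborts the run with a :class:`DivergenceError`
    naming the step and variable.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n_steps = math.ceil(duration / dt)

    specs = [m if isinstance(m, MonitorSpec) else MonitorSpec(m) for m in monitors]
    targets = [(spec, model.find_state(spec.target)) for spec in specs]

    if reset:
        model.reset()
    model.set_rng(np.random.default_rng(seed))

    flat_states = list(model.state_items())
    buffers: dict[str, list] = {spec.target: [] for spec in specs}
    tgrids: dict[str, list] = {spec.target: [] for spec in specs}
    inputs = inputs or {}

    for step in range(n_steps):
        t = step * dt
        inp = {k: _input_value(v, step, t) for k, v in inputs.items()}
        model.update(t, dt, inp)
        for path, sv in flat_states:
            if sv.value.dtype.kind == "f" and not np.all(np.isfinite(sv.value)):
                raise DivergenceError(step, path)
        for spec, sv in targets:
            if (step + 1) % spec.every_n_steps == 0:
                buffers[spec.target].append(np.array(sv.value, copy=True))
                tgrids[spec.target].append((step + 1) * dt)

    series = {k: np.asarray(v) for k, v in buffers.items()}
    times = {k: np.asarray(v) for k, v in tgrids.items()}
    meta = {
        "dt": dt,
        "duration": duration,
        "n_steps": n_steps,
        "seed": seed,
        "model": model.describe(),
        "monitors": [(s.target, s.every_n_steps) for s in specs],
    }
    return SimulationRecord(times=times, series=series, meta=meta)


def batch_run(
    model_factory: Callable[..., DynSystemNode],
    param_grid: Mapping[str, Sequence],
    mode: str = "cartesian",
    **run_kwargs,
) -> list[SimulationRecord]:
    """Run one fresh model per parameter combination; records in grid order.

    ``mode="cartesian"`` takes the cartesian product of the value lists in
    declaration order; ``mode="zip"`` pairs them elementwise (equal lengths
    required).  Each run starts from a freshly built, reset model.
    """
    names = list(param_grid)
    values = [list(param_grid[n]) for n in names]
    if mode == "cartesian":
        combos = [dict(zip(names, c)) for c in itertools.product(*values)] if names else []
    elif mode == "zip":
        lengths = {len(v) for v in values}
        if len(lengths) > 1:
            raise GridError(f"zipped grid lengths differ: { {n: len(v) for n, v in zip(names, values)} }")
        combos = [dict(zip(names, c)) for c in zip(*values)] if names else []
    else:
        raise GridError(f"unknown grid mode {mode!r}")

    records = []
    for combo in combos:
        model = model_factory(**combo)
        rec = run(model, **run_kwargs)
        rec.meta["params"] = dict(combo)
        records.append(rec)
    return records
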