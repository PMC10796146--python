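"""Reference neural models built on the core tree, toolbox, and integrators.

Conventions used throughout:

* voltages in mV, time in ms, rates in Hz;
* conductances are nonnegative and synaptic/channel currents follow
  ``I = g * (E_rev - V)``, added to the membrane equation;
* spikes are detected as ``V >= V_th`` after the integration substep, without
  threshold interpolation;
* membrane and gating equations are advanced by exponential Euler, which is
  exact for their linear parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .core import DynSystemNode
from .errors import ParameterError
from .integrators import exp_euler_step, ode_step
from .sparse import CSRMatrix, event_csr_matvec
from .toolbox import fixed_prob_conn, ring_gaussian_weights

__all__ = [
    "LIFParams",
    "lif_update",
    "LIFPopulation",
    "lif_isi_closed_form",
    "GateSpec",
    "IonChannel",
    "PotassiumChannel",
    "SodiumChannel",
    "CondNeuron",
    "build_hh_neuron",
    "SynapseKernel",
    "make_synapse",
    "synapse_update",
    "dual_exp_peak_time",
    "COBANetwork",
    "build_coba",
    "CANNParams",
    "CANNNetwork",
    "cann_update",
    "cann_derivative",
    "FHNParams",
    "fhn_derivatives",
    "FHNNode",
    "WCParams",
    "wc_derivatives",
    "DecisionRateParams",
    "decision_derivatives",
]


# ---------------------------------------------------------------------------
# Leaky integrate-and-fire
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire constants (times ms, voltages mV)."""

    tau: float = 20.0
    V_rest: float = -65.0
    V_reset: float = -70.0
    V_th: float = -50.0
    R: float = 1.0
    t_ref: float = 2.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ParameterError("membrane time constant must be positive")
        if self.V_reset >= self.V_th:
            raise ParameterError("need V_reset < V_th")


def lif_update(p: LIFParams, V, refr, I, t: float, dt: float):
    """One LIF step: returns ``(V', refr', spike)``.

    Subthreshold dynamics ``tau dV/dt = -(V - V_rest) + R*I`` are integrated
    by exponential Euler (exact for constant input).  Neurons inside their
    refractory window are clamped to ``V_reset``.
    """
    V = np.asarray(V, dtype=float)
    refr = np.asarray(refr, dtype=float)
    I = np.broadcast_to(np.asarray(I, dtype=float), V.shape)
    active = refr <= 0.0
    V_int = exp_euler_step(-1.0 / p.tau, (p.V_rest + p.R * I) / p.tau, V, t, dt)
    V_new = np.where(active, V_int, p.V_reset)
    spike = active & (V_new >= p.V_th)
    V_new = np.where(spike, p.V_reset, V_new)
    refr_new = np.where(spike, p.t_ref, np.maximum(refr - dt, 0.0))
    return V_new, refr_new, spike


def lif_isi_closed_form(p: LIFParams, I: float) -> float:
    """Interspike interval under constant suprathreshold current."""
    drive = p.V_rest + p.R * I
    if drive <= p.V_th:
        return math.inf
    return p.t_ref + p.tau * math.log((drive - p.V_reset) / (drive - p.V_th))


class LIFPopulation(DynSystemNode):
    """A population of LIF neurons driven by input ``I`` (scalar or per-neuron)."""

    def __init__(self, n: int = 1, params: LIFParams | None = None,
                 name: str = "lif", V0: float | np.ndarray | None = None):
        super().__init__(name=name, n=n)
        self.p = params or LIFParams()
        V_init = self.p.V_rest if V0 is None else V0
        self.add_state("V", np.broadcast_to(np.asarray(V_init, float), (n,)).copy())
        self.add_state("refr", np.zeros(n))
        self.add_state("spike", np.zeros(n, dtype=bool))

    def own_update(self, t, dt, inputs):
        I = inputs.get("I", 0.0)
        V, refr, spike = lif_update(
            self.p, self.states["V"].value, self.states["refr"].value, I, t, dt
        )
        self.states["V"].set(V)
        self.states["refr"].set(refr)
        self.states["spike"].set(spike)


# ---------------------------------------------------------------------------
# Hodgkin–Huxley conductance neuron built from ion-channel children
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: forward/backward rates and its exponent."""

    alpha: Callable[[np.ndarray], np.ndarray]
    beta: Callable[[np.ndarray], np.ndarray]
    exponent: int = 1


class IonChannel(DynSystemNode):
    """A voltage-gated channel; contributes ``g_max * prod(x^p)`` conductance.

    Gates follow ``dx/dt = alpha(V)(1-x) - beta(V)x``, advanced by
    exponential Euler, which keeps each gate inside [0, 1].  The membrane
    voltage is read from the parent node's ``V`` state.
    """

    def __init__(self, name: str, g_max: float, E_rev: float,
                 gates: Mapping[str, GateSpec], V_init: float = -65.0, n: int = 1):
        super().__init__(name=name, g_max=g_max, E_rev=E_rev)
        self.gates = dict(gates)
        for gname, spec in self.gates.items():
            a = np.asarray(spec.alpha(np.full(n, V_init)), dtype=float)
            b = np.asarray(spec.beta(np.full(n, V_init)), dtype=float)
            self.add_state(gname, a / (a + b))

    def _membrane_V(self) -> np.ndarray:
        if self.parent is None or "V" not in self.parent.states:
            raise ParameterError(
                f"channel {self.name!r} must be composed under a neuron with a V state"
            )
        return self.parent.states["V"].value

    def own_update(self, t, dt, inputs):
        V = self._membrane_V()
        for gname, spec in self.gates.items():
            a = np.asarray(spec.alpha(V), dtype=float)
            b = np.asarray(spec.beta(V), dtype=float)
            x = self.states[gname].value
            self.states[gname].set(exp_euler_step(-(a + b), a, x, t, dt))

    def conductance(self) -> np.ndarray:
        g = np.asarray(self.params["g_max"], dtype=float)
        for gname, spec in self.gates.items():
            g = g * self.states[gname].value ** spec.exponent
        return g

    def current(self, V) -> np.ndarray:
        return self.conductance() * (self.params["E_rev"] - V)


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    return np.where(small, y * (1.0 + x / (2.0 * y)), x / (1.0 - np.exp(-x / y)))


# Classical squid-axon kinetics (6.3 degC conventions, resting potential -65 mV)
def _alpha_n(V):
    return 0.01 * _vtrap(V + 55.0, 10.0)


def _beta_n(V):
    return 0.125 * np.exp(-(V + 65.0) / 80.0)


def _alpha_m(V):
    return 0.1 * _vtrap(V + 40.0, 10.0)


def _beta_m(V):
    return 4.0 * np.exp(-(V + 65.0) / 18.0)


def _alpha_h(V):
    return 0.07 * np.exp(-(V + 65.0) / 20.0)


def _beta_h(V):
    return 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


def PotassiumChannel(g_max: float = 36.0, E_rev: float = -77.0,
                     V_init: float = -65.0, n: int = 1) -> IonChannel:
    """Delayed-rectifier K+ channel, ``I = g_max n^4 (E_K - V)``."""
    return IonChannel("IK", g_max, E_rev,
                      {"n": GateSpec(_alpha_n, _beta_n, 4)}, V_init=V_init, n=n)


def SodiumChannel(g_max: float = 120.0, E_rev: float = 50.0,
                  V_init: float = -65.0, n: int = 1) -> IonChannel:
    """Transient Na+ channel, ``I = g_max m^3 h (E_Na - V)``."""
    return IonChannel(
        "INa", g_max, E_rev,
        {"m": GateSpec(_alpha_m, _beta_m, 3), "h": GateSpec(_alpha_h, _beta_h, 1)},
        V_init=V_init, n=n,
    )


class CondNeuron(DynSystemNode):
    """Conductance-based neuron integrating the currents of channel children.

    ``C dV/dt = g_L (E_L - V) + sum_channels g_x (E_x - V) + I_ext``.
    Channel children update their gates (using the current V) before the
    neuron integrates V by exponential Euler.
    """

    def __init__(self, name: str = "neuron", C: float = 1.0, g_L: float = 0.3,
                 E_L: float = -54.387, V_init: float = -65.0, n: int = 1,
                 spike_threshold: float = 0.0):
        super().__init__(name=name, C=C, g_L=g_L, E_L=E_L)
        self.n = n
        self.spike_threshold = spike_threshold
        self.add_state("V", np.full(n, float(V_init)))
        self.add_state("spike", np.zeros(n, dtype=bool))

    def own_update(self, t, dt, inputs):
        V = self.states["V"].value
        I_ext = np.broadcast_to(np.asarray(inputs.get("I", 0.0), float), V.shape)
        g_tot = np.full_like(V, self.params["g_L"])
        gE = self.params["g_L"] * self.params["E_L"] * np.ones_like(V)
        for child in self.children.values():
            if isinstance(child, IonChannel):
                g = child.conductance()
                g_tot = g_tot + g
                gE = gE + g * child.params["E_rev"]
        C = self.params["C"]
        V_new = exp_euler_step(-g_tot / C, (gE + I_ext) / C, V, t, dt)
        self.states["spike"].set(
            (V_new >= self.spike_threshold) & (V < self.spike_threshold)
        )
        self.states["V"].set(V_new)


def build_hh_neuron(n: int = 1, C: float = 1.0, g_Na: float = 120.0,
                    g_K: float = 36.0, g_L: float = 0.3, E_Na: float = 50.0,
                    E_K: float = -77.0, E_L: float = -54.387,
                    V_init: float = -65.0) -> CondNeuron:
    """Classical Hodgkin–Huxley neuron as a composite of channel children."""
    neuron = CondNeuron(name="hh", C=C, g_L=g_L, E_L=E_L, V_init=V_init, n=n)
    neuron.add_child(SodiumChannel(g_Na, E_Na, V_init=V_init, n=n), "INa")
    neuron.add_child(PotassiumChannel(g_K, E_K, V_init=V_init, n=n), "IK")
    return neuron


# ---------------------------------------------------------------------------
# Synapse kernels
# ---------------------------------------------------------------------------


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of the normalized difference-of-exponentials kernel."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


class SynapseKernel:
    """Linear synaptic kernel with exact per-step exponential decay.

    ``kind`` is one of ``delta``, ``expon``, ``dual_exp``, ``alpha``,
    ``nmda``.  ``step(increments, dt)`` advances the kernel and injects the
    summed presynaptic drive (one entry per postsynaptic neuron); a unit
    increment produces a conductance transient peaking at ``g_max``.
    ``current(V_post)`` applies the output mode: ``conductance``
    (``I = g (E_rev - V)``), ``current`` (``I = g``), or the NMDA
    magnesium-block factor ``1/(1 + [Mg]/3.57 exp(-0.062 V))`` on top of the
    conductance form.
    """

    def __init__(self, kind: str, n: int, g_max: float = 1.0,
                 tau: float = 5.0, tau_rise: float = 0.5, tau_decay: float = 8.0,
                 E_rev: float = 0.0, mode: str = "conductance", mg: float = 1.0):
        if kind not in ("delta", "expon", "dual_exp", "alpha", "nmda"):
            raise ParameterError(f"unknown synapse kind {kind!r}")
        if mode not in ("conductance", "current"):
            raise ParameterError(f"unknown synapse output mode {mode!r}")
        if kind == "dual_exp" and not tau_rise < tau_decay:
            raise ParameterError("dual_exp needs tau_rise < tau_decay")
        self.kind = kind
        self.n = n
        self.g_max = g_max
        self.tau = tau
        self.tau_rise = tau_rise
        self.tau_decay = tau_decay
        self.E_rev = E_rev
        self.mode = mode
        self.mg = mg
        self.g = np.zeros(n)
        self.h = np.zeros(n)
        if kind in ("dual_exp", "nmda"):
            tp = dual_exp_peak_time(tau_rise, tau_decay)
            self._norm = 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))

    def reset(self):
        self.g[:] = 0.0
        self.h[:] = 0.0

    def step(self, increments, dt: float) -> None:
        inc = np.broadcast_to(np.asarray(increments, dtype=float), (self.n,))
        if self.kind == "delta":
            self.g = self.g_max * inc.copy()
        elif self.kind == "expon":
            self.g = self.g * np.exp(-dt / self.tau) + self.g_max * inc
        elif self.kind in ("dual_exp", "nmda"):
            # g(t) proportional to exp(-t/tau_decay) - exp(-t/tau_rise):
            # both exponentials decay exactly, spikes increment both.
            self.g = self.g * np.exp(-dt / self.tau_decay) + inc
            self.h = self.h * np.exp(-dt / self.tau_rise) + inc
        elif self.kind == "alpha":
            # Jordan-block pair dg/dt=(h-g)/tau, dh/dt=-h/tau, exact step;
            # unit increment peaks at g_max at t = tau.
            decay = np.exp(-dt / self.tau)
            self.g = decay * (self.g + self.h * dt / self.tau)
            self.h = decay * self.h + math.e * self.g_max * inc

    def conductance(self) -> np.ndarray:
        if self.kind in ("dual_exp", "nmda"):
            return self.g_max * self._norm * (self.g - self.h)
        return self.g

    def current(self, V_post) -> np.ndarray:
        g = self.conductance()
        if self.mode == "current":
            return g
        V = np.asarray(V_post, dtype=float)
        I = g * (self.E_rev - V)
        if self.kind == "nmda":
            I = I / (1.0 + self.mg / 3.57 * np.exp(-0.062 * V))
        return I


def make_synapse(kind: str, n: int, **kwargs) -> SynapseKernel:
    return SynapseKernel(kind, n, **kwargs)


def synapse_update(syn: SynapseKernel, events, conn: CSRMatrix | None,
                   V_post, t: float, dt: float) -> np.ndarray:
    """Advance a synapse one step and return the postsynaptic current.

    ``events`` is the presynaptic boolean spike vector; ``conn`` maps events
    to per-postsynaptic-neuron increments through the event-driven operator
    (``None`` means a one-to-one identity mapping).
    """
    events = np.asarray(events, dtype=bool)
    if conn is None:
        inc = events.astype(float)
    else:
        inc = event_csr_matvec(conn, events)
    syn.step(inc, dt)
    return syn.current(V_post)


# ---------------------------------------------------------------------------
# COBA E/I balanced network
# ---------------------------------------------------------------------------


class COBANetwork(DynSystemNode):
    """Sparse E/I balanced network of conductance-based LIF neurons.

    Membrane (conductances in units of the leak conductance):
    ``Cm dV/dt = g_l (E_l - V) + g_e (E_e - V) + g_i (E_i - V) + I``
    with exponentially decaying synaptic conductances incremented by
    presynaptic spikes of the current step.  ``mode`` selects the synaptic
    pathway: ``"event"`` uses the event-driven sparse operator, ``"dense"``
    an equivalent dense masked product — the two produce identical spike
    rasters for equal seeds because per-step increments are integer spike
    counts times a common scalar weight.
    """

    def __init__(self, n_exc: int = 320, n_inh: int = 80, p: float = 0.02,
                 seed: int = 0, synapse: str = "expon", mode: str = "event",
                 we: float = 0.6, wi: float = 6.7, tau_e: float = 5.0,
                 tau_i: float = 10.0, E_e: float = 0.0, E_i: float = -80.0,
                 g_l: float = 1.0, E_l: float = -60.0, Cm: float = 20.0,
                 V_th: float = -50.0, V_reset: float = -60.0, t_ref: float = 5.0,
                 I_ext: float = 12.0, name: str = "coba"):
        if not (0.0 <= p <= 1.0):
            raise ParameterError("connection probability must be in [0, 1]")
        if mode not in ("event", "dense"):
            raise ParameterError(f"unknown synaptic pathway {mode!r}")
        if synapse != "expon":
            raise ParameterError("COBA network supports the 'expon' synapse kind")
        super().__init__(name=name, n_exc=n_exc, n_inh=n_inh, p=p, seed=seed,
                         we=we, wi=wi, tau_e=tau_e, tau_i=tau_i, E_e=E_e,
                         E_i=E_i, g_l=g_l, E_l=E_l, Cm=Cm, V_th=V_th,
                         V_reset=V_reset, t_ref=t_ref, I_ext=I_ext, mode=mode)
        n = n_exc + n_inh
        self.n = n
        self.mode = mode
        self.conn_e = fixed_prob_conn(n_exc, n, p, seed=seed)
        self.conn_i = fixed_prob_conn(n_inh, n, p, seed=seed + 1)
        if mode == "dense":
            self.We = self.conn_e.to_dense()
            self.Wi = self.conn_i.to_dense()
        init_rng = np.random.default_rng(seed + 2)
        V0 = V_reset + (V_th - V_reset) * init_rng.random(n)
        self.add_state("V", V0)
        self.add_state("refr", np.zeros(n))
        self.add_state("spike", np.zeros(n, dtype=bool))
        self.add_state("ge", np.zeros(n))
        self.add_state("gi", np.zeros(n))

    def own_update(self, t, dt, inputs):
        p = self.params
        V = self.states["V"].value
        refr = self.states["refr"].value
        ge = self.states["ge"].value
        gi = self.states["gi"].value
        I_ext = np.broadcast_to(
            np.asarray(inputs.get("I", p["I_ext"]), float), V.shape
        )

        g_tot = p["g_l"] + ge + gi
        drive = p["g_l"] * p["E_l"] + ge * p["E_e"] + gi * p["E_i"] + I_ext
        Cm = p["Cm"]
        active = refr <= 0.0
        V_int = exp_euler_step(-g_tot / Cm, drive / Cm, V, t, dt)
        V_new = np.where(active, V_int, p["V_reset"])
        spike = active & (V_new >= p["V_th"])
        V_new = np.where(spike, p["V_reset"], V_new)
        refr_new = np.where(spike, p["t_ref"], np.maximum(refr - dt, 0.0))

        s_e = spike[: p["n_exc"]]
        s_i = spike[p["n_exc"]:]
        if self.mode == "event":
            inc_e = event_csr_matvec(self.conn_e, s_e)
            inc_i = event_csr_matvec(self.conn_i, s_i)
        else:
            inc_e = s_e.astype(np.float64) @ self.We
            inc_i = s_i.astype(np.float64) @ self.Wi
        ge_new = ge * np.exp(-dt / p["tau_e"]) + p["we"] * inc_e
        gi_new = gi * np.exp(-dt / p["tau_i"]) + p["wi"] * inc_i

        self.states["V"].set(V_new)
        self.states["refr"].set(refr_new)
        self.states["spike"].set(spike)
        self.states["ge"].set(ge_new)
        self.states["gi"].set(gi_new)


def build_coba(n_exc: int = 320, n_inh: int = 80, p: float = 0.02, seed: int = 0,
               synapse: str = "expon", mode: str = "event", **kwargs) -> COBANetwork:
    """Build the E/I balanced conductance-based benchmark network."""
    return COBANetwork(n_exc=n_exc, n_inh=n_inh, p=p, seed=seed,
                       synapse=synapse, mode=mode, **kwargs)


# ---------------------------------------------------------------------------
# Continuous attractor neural network on a ring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CANNParams:
    """Ring attractor network with divisive normalization.

    ``tau du/dt = -u + W r(u) + I_ext`` with
    ``r = u_+^2 / (1 + k rho dx sum(u_+^2))`` and Gaussian ring coupling of
    peak ``J0`` and width ``a`` on a ring of circumference ``L`` (density
    ``rho = N/L``).  With ``k > 0`` the divisive term keeps activity bounded.
    """

    N: int = 128
    tau: float = 1.0
    k: float = 8.1
    a: float = 0.5
    J0: float = 4.0
    L: float = 2 * np.pi

    @property
    def rho(self) -> float:
        return self.N / self.L

    @property
    def dx(self) -> float:
        return self.L / self.N

    def positions(self) -> np.ndarray:
        return np.arange(self.N) * self.dx

    def weights(self) -> np.ndarray:
        # rho * dx = 1, so the Riemann sum of the coupling integral is W @ r
        return ring_gaussian_weights(self.N, self.J0, self.a, self.L)


def _cann_rate(p: CANNParams, u: np.ndarray) -> np.ndarray:
    u_plus = np.maximum(u, 0.0)
    u2 = u_plus * u_plus
    return u2 / (1.0 + p.k * p.rho * p.dx * np.sum(u2))


def cann_update(p: CANNParams, u, Iext, t: float, dt: float,
                W: np.ndarray | None = None) -> np.ndarray:
    """One exponential-Euler step of the ring attractor dynamics."""
    u = np.asarray(u, dtype=float)
    W = p.weights() if W is None else W
    drive = W @ _cann_rate(p, u) + np.broadcast_to(np.asarray(Iext, float), u.shape)
    return exp_euler_step(-1.0 / p.tau, drive / p.tau, u, t, dt)


def cann_derivative(p: CANNParams, W: np.ndarray | None = None):
    """Return ``F(u) = du/dt`` for analyzers (fixed points of the flow)."""
    W = p.weights() if W is None else W

    def F(u):
        u = np.asarray(u, dtype=float)
        return (-u + W @ _cann_rate(p, u)) / p.tau

    return F


def cann_bump(p: CANNParams, center: float, amplitude: float) -> np.ndarray:
    """Gaussian bump profile on the ring (useful as stimulus or ansatz)."""
    x = p.positions()
    diff = np.abs(x - center)
    d = np.minimum(diff, p.L - diff)
    return amplitude * np.exp(-(d ** 2) / (4.0 * p.a ** 2))


class CANNNetwork(DynSystemNode):
    """Ring attractor network node; input ``Iext`` per neuron."""

    def __init__(self, params: CANNParams | None = None, name: str = "cann"):
        super().__init__(name=name)
        self.p = params or CANNParams()
        self.W = self.p.weights()
        self.add_state("u", np.zeros(self.p.N))

    def own_update(self, t, dt, inputs):
        Iext = inputs.get("Iext", 0.0)
        self.states["u"].set(
            cann_update(self.p, self.states["u"].value, Iext, t, dt, W=self.W)
        )

    def bump(self, center: float, amplitude: float) -> np.ndarray:
        return cann_bump(self.p, center, amplitude)


# ---------------------------------------------------------------------------
# Low-dimensional rate models (right-hand sides for simulation and analysis)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh–Nagumo: fast voltage v, slow recovery w."""

    a: float = 0.7
    b: float = 0.8
    tau: float = 12.5
    Iext: float = 0.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ParameterError("tau must be positive")


def fhn_derivatives(p: FHNParams, v, w, t: float = 0.0):
    """``dv = v - v^3/3 - w + Iext``, ``dw = (v + a - b w)/tau``."""
    dv = v - v ** 3 / 3.0 - w + p.Iext
    dw = (v + p.a - p.b * w) / p.tau
    return dv, dw


class FHNNode(DynSystemNode):
    """FitzHugh–Nagumo oscillator integrated with RK4."""

    def __init__(self, params: FHNParams | None = None, name: str = "fhn",
                 v0: float = 0.0, w0: float = 0.0):
        super().__init__(name=name)
        self.p = params or FHNParams()
        self.add_state("v", np.asarray(float(v0)))
        self.add_state("w", np.asarray(float(w0)))

    def own_update(self, t, dt, inputs):
        Iext = float(np.asarray(inputs.get("Iext", self.p.Iext)))
        p = FHNParams(a=self.p.a, b=self.p.b, tau=self.p.tau, Iext=Iext)

        def rhs(tt, y):
            dv, dw = fhn_derivatives(p, y[0], y[1], tt)
            return np.array([dv, dw])

        y = np.array([self.states["v"].value, self.states["w"].value], dtype=float)
        y = ode_step(rhs, y, t, dt, method="rk4")
        self.states["v"].set(y[0])
        self.states["w"].set(y[1])


@dataclass(frozen=True)
class WCParams:
    """Wilson–Cowan population rates with logistic gain functions."""

    w_EE: float = 16.0
    w_EI: float = 12.0
    w_IE: float = 15.0
    w_II: float = 3.0
    a_E: float = 1.3
    theta_E: float = 4.0
    a_I: float = 2.0
    theta_I: float = 3.7
    tau_E: float = 8.0
    tau_I: float = 8.0
    I_E: float = 0.0
    I_I: float = 0.0


def _sigmoid(x, gain, theta):
    return 1.0 / (1.0 + np.exp(-gain * (x - theta)))


def wc_derivatives(p: WCParams, e, i, t: float = 0.0):
    """Standard sigmoid rate equations; activities bounded in [0, 1]."""
    de = (-e + _sigmoid(p.w_EE * e - p.w_EI * i + p.I_E, p.a_E, p.theta_E)) / p.tau_E
    di = (-i + _sigmoid(p.w_IE * e - p.w_II * i + p.I_I, p.a_I, p.theta_I)) / p.tau_I
    return de, di


@dataclass(frozen=True)
class DecisionRateParams:
    """Two-variable reduced decision-making model (gating variables s1, s2).

    The effective transfer function is ``H(x) = (a x - b)/(1 - exp(-d(a x - b)))``
    (x in nA, H in Hz) and each gating variable follows
    ``ds/dt = -s/tau_s + (1 - s) gamma H / 1000`` (time in ms).  The stimulus
    to population 1/2 is ``JA_ext mu0 (1 +/- coh/100)``.
    """

    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641
    tau_s: float = 100.0
    J11: float = 0.2609
    J22: float = 0.2609
    J12: float = 0.0497
    J21: float = 0.0497
    I0: float = 0.3255
    JA_ext: float = 5.2e-4
    mu0: float = 0.0
    coh: float = 0.0


def _decision_H(p: DecisionRateParams, x):
    u = p.a * x - p.b
    du = p.d * u
    small = np.abs(du) < 1e-9
    safe = np.where(small, 1.0, -np.expm1(-du))
    return np.where(small, 1.0 / p.d + u / 2.0, u / safe)


def decision_derivatives(p: DecisionRateParams, s1, s2, t: float = 0.0):
    """Right-hand sides of the two gating variables (per ms)."""
    I_stim1 = p.JA_ext * p.mu0 * (1.0 + p.coh / 100.0)
    I_stim2 = p.JA_ext * p.mu0 * (1.0 - p.coh / 100.0)
    x1 = p.J11 * s1 - p.J12 * s2 + p.I0 + I_stim1
    x2 = p.J22 * s2 - p.J21 * s1 + p.I0 + I_stim2
    ds1 = -s1 / p.tau_s + (1.0 - s1) * p.gamma * _decision_H(p, x1) / 1000.0
    ds2 = -s2 / p.tau_s + (1.0 - s2) * p.gamma * _decision_H(p, x2) / 1000.0
    return ds1, ds2
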