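"""Model zoo: LIF, Hodgkin–Huxley, synapses, COBA, CANN, 2-D rate models."""

import numpy as np
import pytest
import scipy.optimize

import braindyn as bd
from braindyn.errors import ParameterError
from braindyn.zoo import (
    CANNNetwork,
    CANNParams,
    DecisionRateParams,
    FHNParams,
    GateSpec,
    IonChannel,
    LIFParams,
    LIFPopulation,
    SynapseKernel,
    WCParams,
    build_coba,
    build_hh_neuron,
    cann_bump,
    cann_update,
    decision_derivatives,
    dual_exp_peak_time,
    fhn_derivatives,
    lif_isi_closed_form,
    wc_derivatives,
)
from braindyn.zoo import _alpha_h, _alpha_m, _alpha_n, _beta_h, _beta_m, _beta_n


# -- LIF --------------------------------------------------------------------


def test_lif_subthreshold_never_spikes():
    p = LIFParams()
    I = 0.9 * (p.V_th - p.V_rest) / p.R
    rec = bd.run(LIFPopulation(params=p), 500.0, 0.1, inputs={"I": I},
                 monitors=["spike", "V"])
    assert not rec["spike"].any()
    assert rec["V"].max() < p.V_th


def test_lif_at_rest_stays_at_rest():
    p = LIFParams()
    rec = bd.run(LIFPopulation(params=p), 100.0, 0.1, monitors=["V"])
    np.testing.assert_allclose(rec["V"], p.V_rest, atol=1e-12)


@pytest.mark.parametrize("I", [16.0, 20.0, 30.0])
def test_lif_isi_matches_closed_form(I):
    p = LIFParams()
    rec = bd.run(LIFPopulation(params=p), 400.0, 0.01, inputs={"I": I},
                 monitors=["spike"])
    steps = np.flatnonzero(rec["spike"][:, 0])
    isis = np.diff(steps) * 0.01
    assert len(isis) >= 3
    expected = lif_isi_closed_form(p, I)
    assert abs(isis[-1] - expected) / expected < 0.01


def test_lif_params_validated():
    with pytest.raises(ParameterError):
        LIFParams(V_reset=-50.0, V_th=-55.0)


# -- Hodgkin–Huxley ---------------------------------------------------------


def test_hh_rest_gates_reach_steady_state():
    rec = bd.run(build_hh_neuron(), 200.0, 0.01,
                 monitors=["V", "IK.n", "INa.m", "INa.h"])
    V = rec["V"][-1, 0]
    for path, (alpha, beta) in {
        "IK.n": (_alpha_n, _beta_n),
        "INa.m": (_alpha_m, _beta_m),
        "INa.h": (_alpha_h, _beta_h),
    }.items():
        steady = alpha(V) / (alpha(V) + beta(V))
        assert abs(rec[path][-1, 0] - steady) < 1e-4


def test_hh_step_current_spikes_repeatably():
    count = []
    for _ in range(2):
        rec = bd.run(build_hh_neuron(), 500.0, 0.01, inputs={"I": 10.0},
                     monitors=["spike"], seed=0)
        count.append(int(rec["spike"].sum()))
    assert count[0] > 0
    assert count[0] == count[1]


def test_hh_gates_stay_in_unit_interval_under_fuzzing():
    neuron = build_hh_neuron(n=100)
    rng = np.random.default_rng(0)
    currents = rng.uniform(-20.0, 40.0, size=(10_000, 100))
    rec = bd.run(neuron, 10_000 * 0.01, 0.01,
                 inputs={"I": currents},
                 monitors=[bd.MonitorSpec("IK.n", 100),
                           bd.MonitorSpec("INa.m", 100),
                           bd.MonitorSpec("INa.h", 100)])
    for key in ("IK.n", "INa.m", "INa.h"):
        assert rec[key].min() >= 0.0 and rec[key].max() <= 1.0


def test_symmetric_kinetics_drive_gate_to_half():
    const = lambda V: np.full_like(np.asarray(V, dtype=float), 0.3)
    chan = IonChannel("sym", g_max=1.0, E_rev=0.0,
                      gates={"x": GateSpec(const, const, 1)})
    host = bd.DynSystemNode(name="host")
    host.add_state("V", np.zeros(1))
    bd.compose(host, chan, "sym")
    host.states["V"].set(np.zeros(1))
    chan.states["x"].set(np.array([0.9]))
    for i in range(5000):
        chan.update(i * 0.1, 0.1, {})
    assert chan.states["x"].value[0] == pytest.approx(0.5, abs=1e-6)


# -- Synapses ---------------------------------------------------------------


def test_synapse_decays_to_zero_without_events():
    syn = SynapseKernel("expon", n=4, g_max=1.0, tau=5.0)
    syn.g[:] = 1.0
    for _ in range(2000):
        syn.step(np.zeros(4), 0.1)
    assert np.all(syn.conductance() < 1e-12)


def test_single_exponential_closed_form():
    tau, g_max, dt = 5.0, 2.0, 0.1
    syn = SynapseKernel("expon", n=1, g_max=g_max, tau=tau)
    syn.step(np.array([1.0]), dt)  # single event at t=0
    trace = [syn.conductance()[0]]
    for _ in range(500):
        syn.step(np.zeros(1), dt)
        trace.append(syn.conductance()[0])
    t = np.arange(501) * dt
    np.testing.assert_allclose(trace, g_max * np.exp(-t / tau), atol=1e-10)


def test_dual_exponential_peak_time_and_height():
    tau_r, tau_d, dt = 0.8, 6.0, 0.01
    syn = SynapseKernel("dual_exp", n=1, g_max=3.0, tau_rise=tau_r,
                        tau_decay=tau_d)
    syn.step(np.array([1.0]), dt)
    trace = []
    for _ in range(3000):
        syn.step(np.zeros(1), dt)
        trace.append(syn.conductance()[0])
    trace = np.asarray(trace)
    t_peak_sim = (np.argmax(trace) + 2) * dt  # event at step 1
    t_peak = dual_exp_peak_time(tau_r, tau_d)
    assert abs(t_peak_sim - t_peak) <= 2 * dt
    assert trace.max() == pytest.approx(3.0, rel=1e-3)


def test_alpha_synapse_peaks_at_tau():
    tau, dt = 4.0, 0.01
    syn = SynapseKernel("alpha", n=1, g_max=1.5, tau=tau)
    syn.step(np.array([1.0]), dt)
    trace = []
    for _ in range(3000):
        syn.step(np.zeros(1), dt)
        trace.append(syn.conductance()[0])
    trace = np.asarray(trace)
    assert abs((np.argmax(trace) + 2) * dt - tau) <= 2 * dt
    assert trace.max() == pytest.approx(1.5, rel=1e-3)


def test_nmda_block_reduces_current_at_hyperpolarization():
    syn = SynapseKernel("nmda", n=1, g_max=1.0, tau_rise=2.0, tau_decay=100.0,
                        E_rev=0.0)
    syn.step(np.array([1.0]), 0.1)
    for _ in range(30):
        syn.step(np.zeros(1), 0.1)
    i_dep = syn.current(np.array([-20.0]))[0]
    i_hyp = syn.current(np.array([-80.0]))[0]
    # driving force is larger at -80, yet magnesium block wins
    assert abs(i_hyp) < abs(i_dep)


def test_unknown_synapse_kind_rejected():
    with pytest.raises(ParameterError):
        SynapseKernel("gaba_q", n=1)


# -- COBA network -----------------------------------------------------------


def test_coba_active_and_pathways_bitwise_identical():
    rec_e = bd.run(build_coba(seed=3, mode="event", p=0.05), 200.0, 0.1,
                   monitors=["spike"], seed=11)
    rec_d = bd.run(build_coba(seed=3, mode="dense", p=0.05), 200.0, 0.1,
                   monitors=["spike"], seed=11)
    assert rec_e["spike"].sum() > 0
    np.testing.assert_array_equal(rec_e["spike"], rec_d["spike"])


def test_coba_unconnected_subthreshold_is_silent():
    net = build_coba(p=0.0, seed=0, I_ext=5.0)  # threshold needs 10 gl*mV
    rec = bd.run(net, 300.0, 0.1, monitors=["spike"])
    assert rec["spike"].sum() == 0


# -- CANN -------------------------------------------------------------------


def test_cann_zero_state_is_fixed():
    p = CANNParams(N=64)
    u = np.zeros(64)
    for i in range(100):
        u = cann_update(p, u, 0.0, i * 0.1, 0.1)
    np.testing.assert_array_equal(u, np.zeros(64))


def test_cann_bump_persists_at_stimulus_center():
    p = CANNParams()
    net = CANNNetwork(p)
    center = 2.0
    stim = cann_bump(p, center, 10.0)
    u = np.zeros(p.N)
    for i in range(800):
        Iext = stim if i < 300 else 0.0
        u = cann_update(p, u, Iext, i * 0.05, 0.05, W=net.W)
    assert u.max() > 0.1
    com = np.angle(np.sum(np.maximum(u, 0.0) * np.exp(1j * p.positions())))
    com %= 2 * np.pi
    assert abs(com - center) < p.dx


def test_cann_translation_symmetry():
    p = CANNParams(N=64)
    net = CANNNetwork(p)
    shift = 8  # lattice sites
    u1 = cann_bump(p, 1.0, 5.0)
    u2 = np.roll(u1, shift)
    for i in range(500):
        u1 = cann_update(p, u1, 0.0, 0.0, 0.05, W=net.W)
        u2 = cann_update(p, u2, 0.0, 0.0, 0.05, W=net.W)
    np.testing.assert_allclose(u2, np.roll(u1, shift), atol=1e-10)


def test_cann_bump_drift_below_lattice_spacing_per_second():
    p = CANNParams()
    net = CANNNetwork(p)
    u = cann_bump(p, np.pi, 10.0)
    dt = 0.05
    for i in range(400):
        u = cann_update(p, u, cann_bump(p, np.pi, 10.0), i * dt, dt, W=net.W)

    def com(u):
        return np.angle(np.sum(np.maximum(u, 0.0) * np.exp(1j * p.positions())))

    c0 = com(u)
    for i in range(int(1000.0 / dt)):  # one second at tau = 1 ms
        u = cann_update(p, u, 0.0, 0.0, dt, W=net.W)
    drift = np.angle(np.exp(1j * (com(u) - c0)))
    assert abs(drift) < p.dx


# -- 2-D rate models --------------------------------------------------------


def test_fhn_single_stable_fixed_point():
    p = FHNParams()
    g = lambda v: v - v ** 3 / 3.0 - (v + p.a) / p.b
    v_star = scipy.optimize.brentq(g, -3.0, 0.0, xtol=1e-14)
    w_star = (v_star + p.a) / p.b
    assert v_star < -1.0
    dv, dw = fhn_derivatives(p, v_star, w_star)
    assert abs(dv) < 1e-12 and abs(dw) < 1e-12
    # cubic is monotone decreasing for b < 1-ish: the root is unique
    vs = np.linspace(-3, 3, 1001)
    assert np.count_nonzero(np.diff(np.sign(g(vs)))) == 1
    # analytic Jacobian eigenvalues: stable
    J = np.array([[1 - v_star ** 2, -1.0], [1.0 / p.tau, -p.b / p.tau]])
    assert np.max(np.real(np.linalg.eigvals(J))) < 0


def test_decision_model_swap_symmetry_at_zero_stimulus():
    p = DecisionRateParams(mu0=0.0)
    for s1, s2 in [(0.1, 0.4), (0.7, 0.2), (0.5, 0.5)]:
        d1, d2 = decision_derivatives(p, s1, s2)
        d1s, d2s = decision_derivatives(p, s2, s1)
        assert d1 == pytest.approx(d2s, abs=1e-15)
        assert d2 == pytest.approx(d1s, abs=1e-15)


def test_wc_zero_coupling_relaxes_to_sigmoid_of_input():
    p = WCParams(w_EE=0.0, w_EI=0.0, w_IE=0.0, w_II=0.0, I_E=5.0, I_I=3.0)
    e, i = 0.2, 0.8
    dt = 0.1
    for step in range(20_000):
        de, di = wc_derivatives(p, e, i)
        e, i = e + dt * de, i + dt * di
    target_e = 1.0 / (1.0 + np.exp(-p.a_E * (p.I_E - p.theta_E)))
    target_i = 1.0 / (1.0 + np.exp(-p.a_I * (p.I_I - p.theta_I)))
    assert e == pytest.approx(target_e, abs=1e-8)
    assert i == pytest.approx(target_i, abs=1e-8)
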