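"""Compartment, gate, synapse and integrator primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexdamage.fixtures import gen_passive_fixture
from cortexdamage.model_core import (
    CompartmentClass, CompartmentParams, ConfigurationError, GateSpec,
    NeuronTemplate, NumericalBlowupError, RateFunction, SynapseSpec,
    SynapseState, axial_conductances, exp_euler_step, gate_update,
    synapse_update,
)

# HH-style gate with explicit alpha/beta rates for oracle comparisons
HH_GATE = GateSpec(
    name="n", exponent=4,
    alpha=RateFunction("linoid", A=0.01 * 10, V0=-55.0, B=10.0),
    beta=RateFunction("exp", A=0.125, V0=-65.0, B=-80.0),
)


def _passive_comp(cid=0, parent=None, length=100.0, diam=2.0, rm=1.0, ra=1.0,
                  cls=CompartmentClass.SOMA):
    return CompartmentParams(
        id=cid, parent_id=parent, length_um=length, diameter_um=diam,
        specific_rm=rm, specific_cm=0.01, specific_ra=ra,
        leak_reversal_mv=-70.0, compartment_class=cls)


class TestGateUpdate:
    def test_steady_state_is_fixed_point(self):
        v = -65.0
        x_inf = HH_GATE.steady_state(v)
        for dt in (0.01, 0.05, 5.0):
            assert gate_update(HH_GATE, x_inf, v, dt) == pytest.approx(x_inf, abs=1e-14)

    def test_large_dt_relaxes_to_steady_state(self):
        assert gate_update(HH_GATE, 0.0, -65.0, 1e6) == pytest.approx(
            HH_GATE.steady_state(-65.0), abs=1e-12)

    def test_matches_rk4_oracle_over_one_step(self):
        # dx/dt = alpha(1-x) - beta x at fixed V is linear; exponential
        # Euler must agree with fine-step RK4 to 1e-8 over one 50 µs step
        v, dt = -65.0, 0.05
        a = float(HH_GATE.alpha(v))
        b = float(HH_GATE.beta(v))
        x = 0.3

        def rhs(x):
            return a * (1.0 - x) - b * x

        n_sub = 1000
        h = dt / n_sub
        y = x
        for _ in range(n_sub):
            k1 = rhs(y)
            k2 = rhs(y + h / 2 * k1)
            k3 = rhs(y + h / 2 * k2)
            k4 = rhs(y + h * k3)
            y += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert gate_update(HH_GATE, x, v, dt) == pytest.approx(y, abs=1e-8)

    def test_nonfinite_voltage_raises(self):
        with pytest.raises(NumericalBlowupError):
            gate_update(HH_GATE, 0.5, float("nan"), 0.05)

    @given(x=st.floats(0.0, 1.0),
           v=st.floats(-120.0, 60.0),
           dt=st.floats(1e-3, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_gate_stays_in_unit_interval(self, x, v, dt):
        out = gate_update(HH_GATE, x, v, dt)
        assert 0.0 <= out <= 1.0


class TestAxialConductances:
    def test_two_identical_compartments_match_series_formula(self):
        # g = 2/(r+r) = 1/r with r = 4·Ra·l/(π·d²)
        comps = [_passive_comp(0),
                 _passive_comp(1, parent=0, cls=CompartmentClass.APICAL_DENDRITE)]
        tpl = NeuronTemplate("t", comps, {})
        g = axial_conductances(tpl)[(1, 0)]
        l, d, ra = 100e-6, 2e-6, 1.0
        expected = math.pi * d * d / (4.0 * ra * l)
        assert g == pytest.approx(expected, rel=1e-12)

    def test_single_compartment_has_no_edges(self):
        tpl = NeuronTemplate("t", [_passive_comp(0)], {})
        assert axial_conductances(tpl) == {}

    def test_doubling_ra_halves_conductance(self):
        def build(ra):
            comps = [_passive_comp(0, ra=ra),
                     _passive_comp(1, parent=0, ra=ra,
                                   cls=CompartmentClass.APICAL_DENDRITE)]
            return axial_conductances(NeuronTemplate("t", comps, {}))[(1, 0)]
        assert build(2.0) == pytest.approx(build(1.0) / 2.0, rel=1e-12)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ConfigurationError):
            _passive_comp(0, diam=0.0)


class TestExpEulerStep:
    def test_rest_is_fixed_point(self):
        g, e = 1e-9, -0.070
        v = exp_euler_step(e, g, g * e, 1e-11, 50e-6)
        assert v == pytest.approx(e, abs=1e-15)

    def test_matches_closed_form_rc_response_exactly(self):
        # exponential Euler is exact for the linear RC step response
        rm, cm, i_amp, area = 1.0, 0.01, 5e-11, 1e-9
        oracle = gen_passive_fixture(rm, cm, i_amp, area_m2=area)
        g = area / rm
        c = area * cm
        dt = 1.0 / oracle.rate_hz
        v = -0.070
        for k in range(1, len(oracle.samples)):
            v = exp_euler_step(v, g, g * (-0.070) + i_amp, c, dt)
            assert v == pytest.approx(oracle.samples[k], abs=1e-12)

    def test_halving_rm_halves_deflection_and_tau(self):
        rm, cm, i_amp, area = 1.0, 0.01, 5e-11, 1e-9
        full = gen_passive_fixture(rm, cm, i_amp, area_m2=area, duration_s=0.2)
        half = gen_passive_fixture(rm * 0.5, cm, i_amp, area_m2=area, duration_s=0.2)
        d_full = full.samples[-1] - full.samples[0]
        d_half = half.samples[-1] - half.samples[0]
        assert d_half == pytest.approx(d_full / 2.0, rel=1e-6)
        # time constant: 63.2% point at t = tau = Rm·Cm
        for fix, rm_k in ((full, 1.0), (half, 0.5)):
            tau = rm_k * rm * cm
            idx = int(round(tau * fix.rate_hz))
            frac = (fix.samples[idx] - fix.samples[0]) / (fix.samples[-1] - fix.samples[0])
            assert frac == pytest.approx(1 - 1 / math.e, abs=0.01)

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(ValueError):
            exp_euler_step(-0.07, 0.0, 0.0, 1e-11, 50e-6)


class TestSynapseUpdate:
    SYN = SynapseSpec("AMPA", 1e-9, rise_tau_ms=0.5, decay_tau_ms=3.0,
                      reversal_mv=0.0)

    def _run(self, arrivals_at_step, n_steps, dt=0.05, weight=1.0):
        state = SynapseState()
        gs = []
        for k in range(n_steps):
            arr = [1.0] if k in arrivals_at_step else []
            state, g = synapse_update(self.SYN, state, arr, -70.0, dt,
                                      weight=weight)
            gs.append(g)
        return np.asarray(gs)

    def test_no_arrivals_means_zero_conductance(self):
        assert np.all(self._run(set(), 200) == 0.0)

    def test_peak_at_analytic_time_with_unit_amplitude(self):
        dt = 0.01
        gs = self._run({0}, 2000, dt=dt)
        t_peak = self.SYN.peak_time_ms
        assert np.argmax(gs) * dt == pytest.approx(t_peak, abs=2 * dt)
        assert gs.max() == pytest.approx(self.SYN.max_conductance_s, rel=1e-3)

    def test_two_arrivals_superpose_linearly(self):
        g1 = self._run({0}, 400)
        g2 = self._run({100}, 400)
        g12 = self._run({0, 100}, 400)
        np.testing.assert_allclose(g12, g1 + g2, atol=1e-18)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ConfigurationError):
            SynapseSpec("AMPA", 1e-9, rise_tau_ms=3.0, decay_tau_ms=0.5,
                        reversal_mv=0.0)


class TestTemplateValidation:
    def test_cycle_detected(self):
        comps = [_passive_comp(0),
                 _passive_comp(1, parent=2, cls=CompartmentClass.AXON),
                 _passive_comp(2, parent=1, cls=CompartmentClass.AXON)]
        with pytest.raises(ConfigurationError):
            NeuronTemplate("bad", comps, {})

    def test_single_root_required(self):
        comps = [_passive_comp(0), _passive_comp(1)]
        with pytest.raises(ConfigurationError):
            NeuronTemplate("bad", comps, {})


class TestStepNetwork:
    def test_rest_without_drive_stays_quiet(self):
        from cortexdamage.engine import Simulation
        from cortexdamage.network_builder import single_cell_network

        net = single_cell_network("L23_RS_pyramid")
        sim = Simulation(net)
        rec = sim.run(0.5)
        assert len(rec.spikes) == 0
        # converged near rest, well within the blow-up bounds
        assert abs(rec.soma_v[0, -1] * 1e3 + 70.0) < 2.0

    def test_sustained_current_gives_stable_periodic_spiking(self, single_rs_cell_run):
        times = np.array([s.time_s for s in single_rs_cell_run.spikes])
        assert len(times) > 20
        isi = np.diff(times[-11:])
        assert isi.std() / isi.mean() < 0.01

    def test_identical_runs_are_bit_identical(self):
        from cortexdamage.engine import Simulation
        from cortexdamage.network_builder import build_network, desk_scale_config

        cfg = desk_scale_config(seed=77)
        recs = []
        for _ in range(2):
            rec = Simulation(build_network(cfg)).run(0.5)
            recs.append(rec)
        np.testing.assert_array_equal(recs[0].lfp, recs[1].lfp)
        np.testing.assert_array_equal(recs[0].soma_v, recs[1].soma_v)
        assert [(s.neuron_id, s.time_s) for s in recs[0].spikes] == \
               [(s.neuron_id, s.time_s) for s in recs[1].spikes]

    def test_halving_dt_changes_spike_count_by_at_most_two_percent(self):
        from cortexdamage.engine import Simulation
        from cortexdamage.network_builder import single_cell_network

        net = single_cell_network("L23_RS_pyramid")
        counts = []
        for dt in (50e-6, 25e-6):
            sim = Simulation(net, dt_s=dt)
            sim.inject_current(0, 0, 0.2e-9)
            counts.append(len(sim.run(5.0, record_soma=False).spikes))
        assert abs(counts[0] - counts[1]) / counts[1] <= 0.02

    def test_voltage_bounds_guard_trips_on_absurd_input(self):
        from cortexdamage.engine import Simulation
        from cortexdamage.network_builder import single_cell_network

        net = single_cell_network("L23_RS_pyramid")
        sim = Simulation(net)
        sim.inject_current(0, 0, 1e-6)       # 1 µA into one soma
        with pytest.raises(NumericalBlowupError):
            sim.run(0.5, record_soma=False)

    def test_voltage_stays_in_physiological_bounds(self, single_rs_cell_run):
        v_mv = single_rs_cell_run.soma_v * 1e3
        assert v_mv.min() >= -150.0 and v_mv.max() <= 80.0
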