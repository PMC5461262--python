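"""Vectorised network integrator.

The compiled network flattens every compartment, channel gate and synapse
of the whole population into contiguous arrays, advanced together by
exponential Euler at a fixed step (50 µs by default).  Gate steady states
and relaxation factors exp(−dt/τ(V)) are pre-tabulated on a fine voltage
grid (0.02 mV), the standard tabulated-kinetics trick of compartmental
simulators, so a step costs a handful of gathers and bincounts regardless
of channel diversity.

Update order within a step (staggered, standard for exponential Euler):
gates from V(t) → channel and synaptic conductances → voltages → spike
threshold test.  Spikes are detected at each neuron's soma as an upward
crossing of the template threshold outside the refractory window and are
delivered to target synapses after their conduction delay as all-or-none
events.  Everything is deterministic given the network (drive event times
are part of the network, fixed by its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_core import NumericalBlowupError, axial_conductances, mg_block_factor
from .network_builder import Network

# voltage table grid (mV)
_VMIN, _VMAX, _DV = -150.0, 80.0, 0.02
_NV = int(round((_VMAX - _VMIN) / _DV)) + 1

# hard state bounds for the blow-up detector (V)
_V_LO, _V_HI = -0.150, 0.080
_CHECK_EVERY = 2000

# calcium pool dynamics (arbitrary µM-scale units)
CA_TAU_S = 0.050
CA_PHI = 2.0e11          # µM per (A·s) of inward calcium current
CA_REST_UM = 0.05


@dataclass
class SpikeEvent:
    neuron_id: int
    time_s: float


@dataclass
class RawRecording:
    """Raw 20 kHz model output of one run."""

    lfp: np.ndarray                  # distance-weighted sum, model units, len T
    soma_v: np.ndarray               # (n_neurons, T) float32, volts
    spikes: list[SpikeEvent]
    rate_hz: float
    t0_s: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[0] / self.rate_hz

    def spike_counts(self, n_neurons: Optional[int] = None) -> np.ndarray:
        n = n_neurons if n_neurons is not None else self.soma_v.shape[0]
        counts = np.zeros(n, dtype=int)
        for s in self.spikes:
            counts[s.neuron_id] += 1
        return counts


class CompiledNetwork:
    """Flattened arrays for one network realisation at a fixed dt."""

    def __init__(self, network: Network, dt_s: Optional[float] = None):
        self.network = network
        self.dt = float(dt_s if dt_s is not None else network.config.dt_s)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self._compile()

    # -- compilation -------------------------------------------------------

    def _compile(self) -> None:
        net = self.network
        pos = net.positions
        n_neurons = len(pos)
        self.n_neurons = n_neurons

        comp_v0, comp_c, comp_gl, comp_el = [], [], [], []
        comp_pos = []
        self.comp_neuron = []
        # global compartment index of (neuron, local comp id)
        self.comp_index: dict[tuple[int, int], int] = {}
        soma_idx = np.zeros(n_neurons, dtype=np.int64)
        thr = np.zeros(n_neurons)
        refr_steps = np.zeros(n_neurons, dtype=np.int64)

        edge_i, edge_j, edge_g = [], [], []
        gate_comp, gate_tab, gate_exp = [], [], []
        chan_comp, chan_g, chan_e = [], [], []
        chan_gate1, chan_gate2 = [], []
        kca_chan, kca_pool, kca_kd = [], [], []
        ca_chan, ca_pool_of_chan = [], []
        pool_of_comp: dict[int, int] = {}

        self._gate_specs = []         # unique (GateSpec) in table order
        gate_tab_cache: dict[int, int] = {}

        def table_row(gspec) -> int:
            key = id(gspec)
            if key not in gate_tab_cache:
                gate_tab_cache[key] = len(self._gate_specs)
                self._gate_specs.append(gspec)
            return gate_tab_cache[key]

        xyz = pos[["x_um", "y_um", "z_um"]].to_numpy()
        types = pos["type_name"].to_numpy()
        axial_cache = {t: axial_conductances(tpl) for t, tpl in net.templates.items()}

        gi = 0                        # running global compartment counter
        for n in range(n_neurons):
            tpl = net.templates[types[n]]
            base = gi
            local = {}
            for c in tpl.compartments:
                local[c.id] = gi
                self.comp_index[(n, c.id)] = gi
                comp_v0.append(c.leak_reversal_mv * 1e-3)
                comp_c.append(c.capacitance_f)
                comp_gl.append(c.leak_conductance_s)
                comp_el.append(c.leak_reversal_mv * 1e-3)
                comp_pos.append(xyz[n] + np.asarray(c.offset_um))
                self.comp_neuron.append(n)
                for chspec in tpl.channels_for(c):
                    ci = len(chan_comp)
                    chan_comp.append(gi)
                    chan_g.append(chspec.max_conductance_density * c.area_m2)
                    chan_e.append(chspec.reversal_mv * 1e-3)
                    if chspec.ca_dependent:
                        chan_gate1.append(-1)
                        chan_gate2.append(-1)
                        kca_chan.append(ci)
                        kca_kd.append(chspec.ca_kd_um)
                        pool = pool_of_comp.setdefault(gi, len(pool_of_comp))
                        kca_pool.append(pool)
                    else:
                        gids = []
                        for gspec in chspec.gates:
                            gids.append(len(gate_comp))
                            gate_comp.append(gi)
                            gate_tab.append(table_row(gspec))
                            gate_exp.append(gspec.exponent)
                        chan_gate1.append(gids[0] if gids else -1)
                        chan_gate2.append(gids[1] if len(gids) > 1 else -1)
                    if chspec.is_calcium:
                        ca_chan.append(ci)
                        pool = pool_of_comp.setdefault(gi, len(pool_of_comp))
                        ca_pool_of_chan.append(pool)
                gi += 1
            soma_idx[n] = local[tpl.spike_source]
            thr[n] = tpl.spike_threshold_mv * 1e-3
            refr_steps[n] = max(1, int(round(tpl.refractory_ms * 1e-3 / self.dt)))
            for (cid, pid), g in axial_cache[types[n]].items():
                edge_i.append(local[cid])
                edge_j.append(local[pid])
                edge_g.append(g)

        self.n_comp = gi
        self.v = np.asarray(comp_v0)
        self.c = np.asarray(comp_c)
        self.g_leak = np.asarray(comp_gl)
        self.e_leak = np.asarray(comp_el)
        self.comp_pos_um = np.asarray(comp_pos)
        self.soma_idx = soma_idx
        self.threshold_v = thr
        self.refr_steps = refr_steps
        self.edge_i = np.asarray(edge_i, dtype=np.int64)
        self.edge_j = np.asarray(edge_j, dtype=np.int64)
        self.edge_g = np.asarray(edge_g)
        self.g_axial_sum = (
            np.bincount(self.edge_i, weights=self.edge_g, minlength=self.n_comp)
            + np.bincount(self.edge_j, weights=self.edge_g, minlength=self.n_comp))

        self.gate_comp = np.asarray(gate_comp, dtype=np.int64)
        self.gate_tab = np.asarray(gate_tab, dtype=np.int64)
        self.gate_sq = np.asarray(gate_exp, dtype=np.int64) == 2
        self.chan_comp = np.asarray(chan_comp, dtype=np.int64)
        self.chan_g = np.asarray(chan_g)
        self.chan_e = np.asarray(chan_e)
        chan_gate1 = np.asarray(chan_gate1, dtype=np.int64)
        chan_gate2 = np.asarray(chan_gate2, dtype=np.int64)
        self.vg1_chan = np.nonzero(chan_gate1 >= 0)[0]
        self.vg1_gate = chan_gate1[self.vg1_chan]
        self.vg2_chan = np.nonzero(chan_gate2 >= 0)[0]
        self.vg2_gate = chan_gate2[self.vg2_chan]
        self.kca_chan = np.asarray(kca_chan, dtype=np.int64)
        self.kca_pool = np.asarray(kca_pool, dtype=np.int64)
        self.kca_kd = np.asarray(kca_kd)
        self.ca_chan = np.asarray(ca_chan, dtype=np.int64)
        self.ca_pool_of_chan = np.asarray(ca_pool_of_chan, dtype=np.int64)
        self.n_pools = len(pool_of_comp)

        self._build_tables()
        self._build_synapses()

    def _build_tables(self) -> None:
        vgrid = _VMIN + _DV * np.arange(_NV)
        n_tab = len(self._gate_specs)
        self.xinf_flat = np.empty(n_tab * _NV)
        self.efac_flat = np.empty(n_tab * _NV)
        dt_ms = self.dt * 1e3
        for r, gspec in enumerate(self._gate_specs):
            xinf = np.clip(gspec.steady_state(vgrid), 0.0, 1.0)
            tau = np.maximum(gspec.time_constant_ms(vgrid), 1e-6)
            self.xinf_flat[r * _NV:(r + 1) * _NV] = xinf
            # half-step relaxation factor: gates are advanced to the step
            # midpoint for the conductance evaluation, then completed
            self.efac_flat[r * _NV:(r + 1) * _NV] = np.exp(-0.5 * dt_ms / tau)
        self.mg_tab = mg_block_factor(vgrid)

    def _build_synapses(self) -> None:
        net = self.network
        conn = net.connections
        from .network_builder import ampa_spec, gaba_a_spec, nmda_spec
        cfg = net.config
        specs = {
            "AMPA": ampa_spec(cfg.ampa_gmax_s),
            "NMDA": nmda_spec(cfg.nmda_gmax_s),
            "GABA_A": gaba_a_spec(cfg.gaba_gmax_s),
        }
        dt_ms = self.dt * 1e3

        post_l, geff_l, fa_l, fb_l, e_l, nmda_l = [], [], [], [], [], []
        pre_of_syn = []
        delay_steps = []

        def add_rows(kind, pre_ids, post_ids, comps, weights, delays_ms):
            sp = specs[kind]
            k = sp.peak_norm
            start = sum(len(p) for p in post_l)
            gcomp = np.array([self.comp_index[(p, c)]
                              for p, c in zip(post_ids, comps)], dtype=np.int64)
            post_l.append(gcomp)
            geff_l.append(sp.max_conductance_s * np.asarray(weights) * k)
            fa_l.append(np.full(len(gcomp), math.exp(-dt_ms / sp.rise_tau_ms)))
            fb_l.append(np.full(len(gcomp), math.exp(-dt_ms / sp.decay_tau_ms)))
            e_l.append(np.full(len(gcomp), sp.reversal_mv * 1e-3))
            if sp.mg_block:
                nmda_l.append(start + np.arange(len(gcomp)))
            pre_of_syn.append(np.asarray(pre_ids, dtype=np.int64))
            delay_steps.append(np.maximum(
                1, np.round(np.asarray(delays_ms) * 1e-3 / self.dt).astype(np.int64)))

        if len(conn):
            for kind in ("AMPA", "NMDA", "GABA_A"):
                rows = conn[conn["kind"] == kind]
                if len(rows):
                    add_rows(kind, rows["pre_id"].to_numpy(),
                             rows["post_id"].to_numpy(),
                             rows["post_compartment"].to_numpy(),
                             rows["weight"].to_numpy(),
                             rows["delay_ms"].to_numpy())

        # background drive: one synapse per driven neuron on a distal
        # dendrite (plus an optional slow NMDA component at the same site)
        drv = net.drive
        n_drv = len(drv.driven_ids)
        self.drive_syn_offset = sum(len(p) for p in post_l)
        self._drive_groups = 0
        if n_drv:
            gcomp = np.array([self.comp_index[(int(n), drv.target_of(j))]
                              for j, n in enumerate(drv.driven_ids)], dtype=np.int64)
            drive_specs = [drv.synapse]
            if drv.nmda_synapse is not None:
                drive_specs.append(drv.nmda_synapse)
            self._drive_groups = len(drive_specs)
            for gi_d, sp in enumerate(drive_specs):
                k = sp.peak_norm
                start = sum(len(p) for p in post_l)
                post_l.append(gcomp)
                geff_l.append(np.full(n_drv, sp.max_conductance_s * k))
                fa_l.append(np.full(n_drv, math.exp(-dt_ms / sp.rise_tau_ms)))
                fb_l.append(np.full(n_drv, math.exp(-dt_ms / sp.decay_tau_ms)))
                e_l.append(np.full(n_drv, sp.reversal_mv * 1e-3))
                if sp.mg_block:
                    nmda_l.append(start + np.arange(n_drv))

        if post_l:
            self.syn_post = np.concatenate(post_l)
            self.syn_geff = np.concatenate(geff_l)
            self.syn_fa = np.concatenate(fa_l)
            self.syn_fb = np.concatenate(fb_l)
            self.syn_e = np.concatenate(e_l)
        else:
            self.syn_post = np.empty(0, dtype=np.int64)
            self.syn_geff = self.syn_fa = self.syn_fb = self.syn_e = np.empty(0)
        self.nmda_idx = (np.concatenate(nmda_l).astype(np.int64)
                         if nmda_l else np.empty(0, dtype=np.int64))
        self.n_syn = len(self.syn_post)

        # per-neuron outgoing synapses grouped by delay for event scheduling
        if pre_of_syn:
            pre_all = np.concatenate(pre_of_syn)
            delay_all = np.concatenate(delay_steps)
            syn_ids = np.arange(len(pre_all), dtype=np.int64)
        else:
            pre_all = np.empty(0, dtype=np.int64)
            delay_all = np.empty(0, dtype=np.int64)
            syn_ids = np.empty(0, dtype=np.int64)
        self.max_delay_steps = int(delay_all.max()) if len(delay_all) else 1
        self.outgoing: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(self.n_neurons)]
        order = np.lexsort((delay_all, pre_all))
        pre_s, del_s, ids_s = pre_all[order], delay_all[order], syn_ids[order]
        start = 0
        while start < len(pre_s):
            n = pre_s[start]
            end = start
            while end < len(pre_s) and pre_s[end] == n:
                end += 1
            d_seg, i_seg = del_s[start:end], ids_s[start:end]
            for d in np.unique(d_seg):
                self.outgoing[int(n)].append((int(d), i_seg[d_seg == d]))
            start = end

        # flatten drive events sorted by step; each event hits every drive
        # component synapse of its neuron
        ev_steps, ev_syn = [], []
        n_drv = len(net.drive.driven_ids)
        for k, t in enumerate(net.drive.event_steps):
            for gi_d in range(self._drive_groups):
                ev_steps.append(t)
                ev_syn.append(np.full(len(t), self.drive_syn_offset
                                      + gi_d * n_drv + k, dtype=np.int64))
        if ev_steps:
            steps = np.concatenate(ev_steps)
            syn = np.concatenate(ev_syn)
            order = np.argsort(steps, kind="stable")
            self.drive_event_steps = steps[order]
            self.drive_event_syn = syn[order]
        else:
            self.drive_event_steps = np.empty(0, dtype=np.int64)
            self.drive_event_syn = np.empty(0, dtype=np.int64)


class Simulation:
    """Stateful integrator over a compiled network."""

    def __init__(self, network: Network, dt_s: Optional[float] = None,
                 electrode=None):
        from .recording import ElectrodeSpec, lfp_weights
        self.net = CompiledNetwork(network, dt_s)
        self.dt = self.net.dt
        self.electrode = electrode or ElectrodeSpec.default_for(network.config)
        self.lfp_w = lfp_weights(self.net.comp_pos_um, self.electrode)
        self.reset()

    def reset(self) -> None:
        net = self.net
        self.v = net.v.copy()
        v_mv = self.v * 1e3
        vidx = self._vidx(v_mv)
        flat = net.gate_tab * _NV + vidx[net.gate_comp]
        self.gate_x = net.xinf_flat[flat].copy()
        self.ca = np.full(net.n_pools, CA_REST_UM)
        self.syn_a = np.zeros(net.n_syn)
        self.syn_b = np.zeros(net.n_syn)
        self.last_spike = np.full(net.n_neurons, -10**9, dtype=np.int64)
        self.i_inject = np.zeros(net.n_comp)      # constant injected current, A
        self.v_prev = self.v.copy()
        self.step_count = 0
        L = net.max_delay_steps + 2
        self._ring: list[list[np.ndarray]] = [[] for _ in range(L)]
        self._ring_len = L
        self._drive_ptr = 0
        self.spikes: list[SpikeEvent] = []

    @staticmethod
    def _vidx(v_mv: np.ndarray) -> np.ndarray:
        idx = np.rint((v_mv - _VMIN) / _DV).astype(np.int64)
        return np.clip(idx, 0, _NV - 1)

    def step(self) -> np.ndarray:
        """Advance one dt; returns ids of neurons that spiked this step."""
        net = self.net
        t = self.step_count
        v = self.v
        # gate kinetics evaluated at the extrapolated step midpoint
        # (V + ½ΔV_prev): second-order accurate for the staggered update
        v_mid = 1.5 * v - 0.5 * self.v_prev
        vidx = self._vidx(v_mid * 1e3)

        # gates from V(t + dt/2), extrapolated
        if len(net.gate_comp):
            flat = net.gate_tab * _NV + vidx[net.gate_comp]
            xinf = net.xinf_flat[flat]
            ef = net.efac_flat[flat]
            x_mid = xinf + (self.gate_x - xinf) * ef      # midpoint state
            self.gate_x = xinf + (x_mid - xinf) * ef      # full-step state
            xpow = x_mid.copy()
            sq = net.gate_sq
            xpow[sq] *= x_mid[sq]

        # channel conductances
        g_act = np.zeros(net.n_comp)
        ge_act = np.zeros(net.n_comp)
        if len(net.chan_comp):
            open_frac = np.ones(len(net.chan_comp))
            open_frac[net.vg1_chan] = xpow[net.vg1_gate]
            if len(net.vg2_chan):
                open_frac[net.vg2_chan] *= xpow[net.vg2_gate]
            if len(net.kca_chan):
                caf = self.ca[net.kca_pool]
                open_frac[net.kca_chan] = caf / (caf + net.kca_kd)
            g_ch = net.chan_g * open_frac
            g_act = np.bincount(net.chan_comp, weights=g_ch, minlength=net.n_comp)
            ge_act = np.bincount(net.chan_comp, weights=g_ch * net.chan_e,
                                 minlength=net.n_comp)
            if len(net.ca_chan):
                ic = g_ch[net.ca_chan] * (v[net.chan_comp[net.ca_chan]]
                                          - net.chan_e[net.ca_chan])
                influx = np.bincount(net.ca_pool_of_chan, weights=-ic,
                                     minlength=net.n_pools)
                self.ca = (self.ca * math.exp(-self.dt / CA_TAU_S)
                           + CA_PHI * np.maximum(influx, 0.0) * self.dt)

        # synapses: decay, deliver arrivals, conductance
        if net.n_syn:
            self.syn_a *= net.syn_fa
            self.syn_b *= net.syn_fb
            slot = t % self._ring_len
            pending = self._ring[slot]
            if pending:
                for idxs in pending:
                    np.add.at(self.syn_a, idxs, 1.0)
                    np.add.at(self.syn_b, idxs, 1.0)
                self._ring[slot] = []
            p = self._drive_ptr
            dsteps = net.drive_event_steps
            if p < len(dsteps) and dsteps[p] == t:
                q = p
                while q < len(dsteps) and dsteps[q] == t:
                    q += 1
                ids = net.drive_event_syn[p:q]
                self.syn_a[ids] += 1.0
                self.syn_b[ids] += 1.0
                self._drive_ptr = q
            g_syn = net.syn_geff * (self.syn_b - self.syn_a)
            if len(net.nmda_idx):
                g_syn[net.nmda_idx] *= net.mg_tab[vidx[net.syn_post[net.nmda_idx]]]
            g_s = np.bincount(net.syn_post, weights=g_syn, minlength=net.n_comp)
            ge_s = np.bincount(net.syn_post, weights=g_syn * net.syn_e,
                               minlength=net.n_comp)
        else:
            g_s = ge_s = 0.0

        # axial coupling (neighbour voltages at time t)
        ax_num = (np.bincount(net.edge_i, weights=net.edge_g * v[net.edge_j],
                              minlength=net.n_comp)
                  + np.bincount(net.edge_j, weights=net.edge_g * v[net.edge_i],
                                minlength=net.n_comp))

        g_tot = net.g_leak + g_act + g_s + net.g_axial_sum
        num = net.g_leak * net.e_leak + ge_act + ge_s + ax_num + self.i_inject
        v_inf = num / g_tot
        v_new = v_inf + (v - v_inf) * np.exp(-self.dt * g_tot / net.c)
        # soma threshold crossing, upward, outside refractory
        vs_old = v[net.soma_idx]
        vs_new = v_new[net.soma_idx]
        firing = np.nonzero(
            (vs_old < net.threshold_v) & (vs_new >= net.threshold_v)
            & (t - self.last_spike > net.refr_steps))[0]
        self.v_prev = v
        self.v = v_new
        if len(firing):
            self.last_spike[firing] = t
            tsec = (t + 1) * self.dt
            for n in firing:
                self.spikes.append(SpikeEvent(int(n), tsec))
                for d, idxs in net.outgoing[int(n)]:
                    self._ring[(t + d) % self._ring_len].append(idxs)
        self.step_count = t + 1

        if (self.step_count % _CHECK_EVERY) == 0:
            bad = ~np.isfinite(v_new) | (v_new < _V_LO) | (v_new > _V_HI)
            if bad.any():
                comp = int(np.nonzero(bad)[0][0])
                raise NumericalBlowupError("voltage out of bounds",
                                           step=self.step_count, compartment=comp)
        return firing

    def inject_current(self, neuron_id: int, comp_id: int, amp_a: float) -> None:
        """Set a constant injected current (A) into one compartment."""
        self.i_inject[self.net.comp_index[(neuron_id, comp_id)]] = amp_a

    def lfp_sample(self) -> float:
        """Distance-weighted membrane-potential sum at the electrode."""
        return float(self.lfp_w @ self.v)

    def run(self, duration_s: float, record_soma: bool = True) -> RawRecording:
        n_steps = int(round(duration_s / self.dt))
        lfp = np.empty(n_steps)
        soma = (np.empty((self.net.n_neurons, n_steps), dtype=np.float32)
                if record_soma else np.empty((0, 0), dtype=np.float32))
        soma_idx = self.net.soma_idx
        for k in range(n_steps):
            self.step()
            lfp[k] = self.lfp_w @ self.v
            if record_soma:
                soma[:, k] = self.v[soma_idx]
        return RawRecording(lfp=lfp, soma_v=soma, spikes=list(self.spikes),
                            rate_hz=1.0 / self.dt)


def step_network(sim: Simulation) -> tuple[Simulation, np.ndarray]:
    """Advance a simulation one step; returns (sim, spiking neuron ids)."""
    return sim, sim.step()
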