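"""Compartmental neuron dynamics.

A neuron is a tree of cylindrical compartments, each carrying a leak
conductance, optional Hodgkin-Huxley-style voltage-gated channels and
dual-exponential synaptic conductances.  Adjacent compartments are coupled
through axial conductances derived from the cable equation, and every state
variable is advanced with the exponential Euler scheme, which is exact for
linear membrane dynamics over a step.

Unit conventions
----------------
Geometry and channel kinetics are specified at the interface in the
conventional mix used by compartmental simulators: µm for lengths, mV for
voltages, ms for time constants, Ω·m² / F·m⁻² / Ω·m for specific passive
parameters, S/m² for channel densities.  The time stepping primitives
(`exp_euler_step`) work in SI (volts, siemens, farads, amperes, seconds);
conversion happens at the boundary and nowhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CompartmentClass",
    "CompartmentParams",
    "RateFunction",
    "GateSpec",
    "ChannelSpec",
    "SynapseSpec",
    "SynapseState",
    "NeuronTemplate",
    "NumericalBlowupError",
    "ConfigurationError",
    "gate_update",
    "axial_conductances",
    "exp_euler_step",
    "synapse_update",
    "mg_block_factor",
]


class ConfigurationError(ValueError):
    """A structurally invalid template, network or parameter set."""


class NumericalBlowupError(RuntimeError):
    """Raised when the integrator produces non-finite or runaway state."""

    def __init__(self, message: str, step: Optional[int] = None,
                 compartment: Optional[int] = None):
        self.step = step
        self.compartment = compartment
        if step is not None or compartment is not None:
            message = f"{message} (step={step}, compartment={compartment})"
        super().__init__(message)


class CompartmentClass(str, Enum):
    """Anatomical label of a compartment; damage targeting keys off this."""

    SOMA = "soma"
    AXON_INITIAL_SEGMENT = "axon_initial_segment"
    AXON = "axon"
    BASAL_DENDRITE = "basal_dendrite"
    APICAL_DENDRITE = "apical_dendrite"
    DISTAL_DENDRITE = "distal_dendrite"


AXONAL_CLASSES = frozenset({CompartmentClass.AXON, CompartmentClass.AXON_INITIAL_SEGMENT})
SOMATODENDRITIC_CLASSES = frozenset({
    CompartmentClass.SOMA,
    CompartmentClass.BASAL_DENDRITE,
    CompartmentClass.APICAL_DENDRITE,
    CompartmentClass.DISTAL_DENDRITE,
})


@dataclass
class CompartmentParams:
    """Geometry and passive membrane parameters of one cylinder.

    ``specific_rm`` is the *baseline* (pre-damage) membrane resistance in
    Ω·m²; the damage model rescales the effective value but never mutates
    the baseline.  ``offset_um`` is the compartment center relative to the
    soma center, used for the 3-D placement of the whole tree.
    """

    id: int
    parent_id: Optional[int]
    length_um: float
    diameter_um: float
    specific_rm: float            # Ω·m² (baseline)
    specific_cm: float            # F/m²
    specific_ra: float            # Ω·m
    leak_reversal_mv: float
    compartment_class: CompartmentClass
    offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ConfigurationError(
                f"compartment {self.id}: length and diameter must be positive")
        if self.specific_rm <= 0 or self.specific_cm <= 0 or self.specific_ra <= 0:
            raise ConfigurationError(
                f"compartment {self.id}: passive parameters must be positive")
        self.compartment_class = CompartmentClass(self.compartment_class)

    @property
    def area_m2(self) -> float:
        """Lateral membrane area π·d·l in m²."""
        return math.pi * self.diameter_um * 1e-6 * self.length_um * 1e-6

    @property
    def leak_conductance_s(self) -> float:
        """Baseline leak conductance area/Rm in siemens."""
        return self.area_m2 / self.specific_rm

    @property
    def capacitance_f(self) -> float:
        return self.area_m2 * self.specific_cm

    @property
    def axial_half_resistance_ohm(self) -> float:
        """Resistance from the compartment center to either end: 4·Ra·l/(π·d²)·(1/2)·2.

        Following the standard series formula the full-length resistance is
        r = 4·Ra·l/(π·d²); coupling between neighbours uses g = 2/(r_i+r_j).
        """
        l = self.length_um * 1e-6
        d = self.diameter_um * 1e-6
        return 4.0 * self.specific_ra * l / (math.pi * d * d)


@dataclass(frozen=True)
class RateFunction:
    """Parametric voltage-dependent rate / steady-state form (V in mV).

    forms:
      ``const``    A
      ``exp``      A·exp((V−V0)/B)
      ``sigmoid``  A / (1 + exp(−(V−V0)/B))
      ``linoid``   A·(V−V0) / (1 − exp(−(V−V0)/B)), → A·B at V = V0
      ``sech``     A / (exp((V−V0)/B) + exp(−(V−V0)/B))
    """

    form: str
    A: float
    V0: float = 0.0
    B: float = 1.0

    def __call__(self, v_mv):
        v = np.asarray(v_mv, dtype=float)
        if self.form == "const":
            return np.full_like(v, self.A)
        if self.form == "exp":
            return self.A * np.exp((v - self.V0) / self.B)
        if self.form == "sigmoid":
            return self.A / (1.0 + np.exp(-(v - self.V0) / self.B))
        if self.form == "sech":
            u = (v - self.V0) / self.B
            return self.A / (np.exp(u) + np.exp(-u))
        if self.form == "linoid":
            u = v - self.V0
            with np.errstate(over="ignore", invalid="ignore"):
                out = self.A * u / (1.0 - np.exp(-u / self.B))
            # removable singularity at V0
            out = np.where(np.abs(u) < 1e-7, self.A * self.B, out)
            return out
        raise ConfigurationError(f"unknown rate-function form {self.form!r}")

    def to_dict(self) -> dict:
        return {"form": self.form, "A": self.A, "V0": self.V0, "B": self.B}

    @classmethod
    def from_dict(cls, d: dict) -> "RateFunction":
        return cls(**d)


@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation variable of a channel.

    The kinetics may be given either as transition rates α(V), β(V) (both in
    1/ms) or directly as x_∞(V) and τ_x(V) (ms).  Either way the update rule
    is the exponential relaxation x' = x_∞ + (x − x_∞)·exp(−dt/τ).
    """

    name: str
    exponent: int
    alpha: Optional[RateFunction] = None
    beta: Optional[RateFunction] = None
    inf: Optional[RateFunction] = None
    tau: Optional[RateFunction] = None

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ConfigurationError("gate exponent must be ≥ 1")
        ab = self.alpha is not None and self.beta is not None
        it = self.inf is not None and self.tau is not None
        if not (ab or it):
            raise ConfigurationError(
                f"gate {self.name!r} needs either (alpha, beta) or (inf, tau)")

    def steady_state(self, v_mv):
        if self.inf is not None:
            return self.inf(v_mv)
        a = self.alpha(v_mv)
        b = self.beta(v_mv)
        return a / (a + b)

    def time_constant_ms(self, v_mv):
        if self.tau is not None:
            return self.tau(v_mv)
        return 1.0 / (self.alpha(v_mv) + self.beta(v_mv))

    def to_dict(self) -> dict:
        d = {"name": self.name, "exponent": self.exponent}
        for k in ("alpha", "beta", "inf", "tau"):
            rf = getattr(self, k)
            if rf is not None:
                d[k] = rf.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GateSpec":
        kw = {"name": d["name"], "exponent": d["exponent"]}
        for k in ("alpha", "beta", "inf", "tau"):
            if k in d:
                kw[k] = RateFunction.from_dict(d[k])
        return cls(**kw)


@dataclass(frozen=True)
class ChannelSpec:
    """A voltage-gated (or Ca-gated) conductance on one compartment class.

    ``ca_dependent`` marks Ca-activated potassium channels whose open
    fraction is Ca/(Ca + kd) from a per-compartment calcium pool rather
    than a voltage gate.  ``is_calcium`` marks channels whose current feeds
    that pool.
    """

    name: str
    max_conductance_density: float   # S/m²
    reversal_mv: float
    gates: tuple[GateSpec, ...] = ()
    ca_dependent: bool = False
    ca_kd_um: float = 0.5
    is_calcium: bool = False

    def __post_init__(self) -> None:
        if self.max_conductance_density < 0:
            raise ConfigurationError("channel density must be ≥ 0")
        if not (-120.0 <= self.reversal_mv <= 150.0):
            raise ConfigurationError("channel reversal outside plausible range")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "max_conductance_density_S_per_m2": self.max_conductance_density,
            "reversal_mv": self.reversal_mv,
            "gates": [g.to_dict() for g in self.gates],
            "ca_dependent": self.ca_dependent,
            "ca_kd_um": self.ca_kd_um,
            "is_calcium": self.is_calcium,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSpec":
        return cls(
            name=d["name"],
            max_conductance_density=d["max_conductance_density_S_per_m2"],
            reversal_mv=d["reversal_mv"],
            gates=tuple(GateSpec.from_dict(g) for g in d["gates"]),
            ca_dependent=d.get("ca_dependent", False),
            ca_kd_um=d.get("ca_kd_um", 0.5),
            is_calcium=d.get("is_calcium", False),
        )


@dataclass(frozen=True)
class SynapseSpec:
    """Dual-exponential synaptic conductance.

    g(t) = gbar·w·k·(exp(−t/τ_decay) − exp(−t/τ_rise)) per presynaptic
    event, with k normalising the peak of the transient to 1 so that
    gbar·w is the peak conductance.  NMDA synapses are additionally scaled
    by the sigmoidal magnesium-block factor of the postsynaptic voltage.
    """

    kind: str                       # 'AMPA' | 'NMDA' | 'GABA_A'
    max_conductance_s: float        # S (peak, weight 1)
    rise_tau_ms: float
    decay_tau_ms: float
    reversal_mv: float
    mg_block: bool = False

    def __post_init__(self) -> None:
        if not (self.decay_tau_ms > self.rise_tau_ms > 0):
            raise ConfigurationError("need decay_tau > rise_tau > 0")
        if self.kind == "GABA_A" and self.reversal_mv > -65.0:
            raise ConfigurationError("GABA_A reversal must be hyperpolarising")
        if self.kind in ("AMPA", "NMDA") and self.reversal_mv < 0.0:
            raise ConfigurationError("glutamatergic reversal must be ≥ 0 mV")
        if self.mg_block and self.kind != "NMDA":
            raise ConfigurationError("mg_block is an NMDA-only property")

    @property
    def peak_time_ms(self) -> float:
        """Time to peak of the dual exponential after an arrival."""
        tr, td = self.rise_tau_ms, self.decay_tau_ms
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def peak_norm(self) -> float:
        """1 / (exp(−t_p/τ_d) − exp(−t_p/τ_r)); scales the peak to 1."""
        tp = self.peak_time_ms
        return 1.0 / (math.exp(-tp / self.decay_tau_ms) - math.exp(-tp / self.rise_tau_ms))


@dataclass
class SynapseState:
    """Rise/decay state variables of one dual-exponential synapse."""

    a: float = 0.0   # decays with rise_tau
    b: float = 0.0   # decays with decay_tau


def mg_block_factor(v_mv):
    """Jahr–Stevens voltage-dependent magnesium block, [Mg²⁺] = 1 mM.

    Returns a factor in (0, 1): 1/(1 + exp(−0.062·V)·[Mg]/3.57).
    """
    v = np.asarray(v_mv, dtype=float)
    return 1.0 / (1.0 + np.exp(-0.062 * v) / 3.57)


@dataclass
class NeuronTemplate:
    """One cell type: compartment tree, channel complement, spike rule."""

    type_name: str
    compartments: list[CompartmentParams]
    channels: dict[CompartmentClass, list[ChannelSpec]]
    spike_source: int = 0
    spike_threshold_mv: float = 0.0
    refractory_ms: float = 2.0

    def __post_init__(self) -> None:
        self.channels = {CompartmentClass(k): list(v) for k, v in self.channels.items()}
        self._validate_tree()

    def _validate_tree(self) -> None:
        ids = [c.id for c in self.compartments]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"{self.type_name}: duplicate compartment ids")
        by_id = {c.id: c for c in self.compartments}
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1:
            raise ConfigurationError(
                f"{self.type_name}: compartment tree must have exactly one root")
        if roots[0].compartment_class is not CompartmentClass.SOMA:
            raise ConfigurationError(f"{self.type_name}: root must be the soma")
        if self.spike_source not in by_id:
            raise ConfigurationError(f"{self.type_name}: spike_source not a compartment")
        # acyclicity: walk every compartment to the root
        for c in self.compartments:
            seen, cur = set(), c
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ConfigurationError(f"{self.type_name}: cycle at {cur.id}")
                seen.add(cur.id)
                if cur.parent_id not in by_id:
                    raise ConfigurationError(
                        f"{self.type_name}: dangling parent {cur.parent_id}")
                cur = by_id[cur.parent_id]

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def compartment(self, cid: int) -> CompartmentParams:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def channels_for(self, comp: CompartmentParams) -> list[ChannelSpec]:
        return self.channels.get(comp.compartment_class, [])

    def to_dict(self) -> dict:
        return {
            "type_name": self.type_name,
            "spike_source": self.spike_source,
            "spike_threshold_mv": self.spike_threshold_mv,
            "refractory_ms": self.refractory_ms,
            "compartments": [
                {
                    "id": c.id,
                    "parent_id": c.parent_id,
                    "length_um": c.length_um,
                    "diameter_um": c.diameter_um,
                    "specific_rm_ohm_m2": c.specific_rm,
                    "specific_cm_f_per_m2": c.specific_cm,
                    "specific_ra_ohm_m": c.specific_ra,
                    "leak_reversal_mv": c.leak_reversal_mv,
                    "compartment_class": c.compartment_class.value,
                    "offset_um": list(c.offset_um),
                }
                for c in self.compartments
            ],
            "channels": {
                k.value: [ch.to_dict() for ch in v] for k, v in self.channels.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronTemplate":
        comps = [
            CompartmentParams(
                id=c["id"],
                parent_id=c["parent_id"],
                length_um=c["length_um"],
                diameter_um=c["diameter_um"],
                specific_rm=c["specific_rm_ohm_m2"],
                specific_cm=c["specific_cm_f_per_m2"],
                specific_ra=c["specific_ra_ohm_m"],
                leak_reversal_mv=c["leak_reversal_mv"],
                compartment_class=CompartmentClass(c["compartment_class"]),
                offset_um=tuple(c["offset_um"]),
            )
            for c in d["compartments"]
        ]
        chans = {
            CompartmentClass(k): [ChannelSpec.from_dict(ch) for ch in v]
            for k, v in d["channels"].items()
        }
        return cls(
            type_name=d["type_name"],
            compartments=comps,
            channels=chans,
            spike_source=d["spike_source"],
            spike_threshold_mv=d["spike_threshold_mv"],
            refractory_ms=d["refractory_ms"],
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def gate_update(gate: GateSpec, x, v_mv, dt_ms):
    """Advance a gate one exponential-Euler step at fixed voltage.

    x' = x_∞(V) + (x − x_∞(V))·exp(−dt/τ(V)); exact for the linear gate ODE
    dx/dt = (x_∞ − x)/τ when V is held over the step.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    v = np.asarray(v_mv, dtype=float)
    if not np.all(np.isfinite(v)):
        raise NumericalBlowupError("non-finite voltage passed to gate_update")
    xinf = gate.steady_state(v)
    tau = gate.time_constant_ms(v)
    return xinf + (np.asarray(x, dtype=float) - xinf) * np.exp(-dt_ms / tau)


def axial_conductances(template: NeuronTemplate) -> dict[tuple[int, int], float]:
    """Axial coupling conductance (S) for each parent-child edge.

    g_ij = 2/(r_i + r_j) with r_k = 4·Ra·l_k/(π·d_k²); returned once per
    edge keyed (child_id, parent_id); the coupling is symmetric.
    """
    out: dict[tuple[int, int], float] = {}
    by_id = {c.id: c for c in template.compartments}
    for c in template.compartments:
        if c.parent_id is None:
            continue
        p = by_id[c.parent_id]
        r = c.axial_half_resistance_ohm + p.axial_half_resistance_ohm
        out[(c.id, p.id)] = 2.0 / r
    return out


def exp_euler_step(v, g_total, drive, c, dt):
    """One exponential-Euler voltage step, SI units throughout.

    V' = V_∞ + (V − V_∞)·exp(−dt·g_total/C) with V_∞ = drive/g_total, where
    ``drive`` aggregates Σ g_i·E_i + I_inject + Σ g_axial·V_neighbour (A)
    and ``g_total`` the matching total conductance (S).
    """
    g_total = np.asarray(g_total, dtype=float)
    if np.any(g_total <= 0):
        raise ValueError("g_total must be positive to form a time constant")
    v = np.asarray(v, dtype=float)
    c = np.asarray(c, dtype=float)
    v_inf = np.asarray(drive, dtype=float) / g_total
    return v_inf + (v - v_inf) * np.exp(-dt * g_total / c)


def synapse_update(syn: SynapseSpec, state: SynapseState,
                   spike_arrivals: Sequence[float], v_mv: float, dt_ms: float,
                   weight: float = 1.0) -> tuple[SynapseState, float]:
    """Advance one synapse a step; arrivals are event weights landing now.

    Both state variables decay exponentially over the step; each arrival
    then increments both by weight·k (peak-normalised).  Returns the new
    state and the conductance gbar·(b − a), with NMDA magnesium block
    applied at the postsynaptic voltage.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    fa = math.exp(-dt_ms / syn.rise_tau_ms)
    fb = math.exp(-dt_ms / syn.decay_tau_ms)
    a = state.a * fa
    b = state.b * fb
    for _ in spike_arrivals:
        a += weight * syn.peak_norm
        b += weight * syn.peak_norm
    g = syn.max_conductance_s * (b - a)
    if syn.mg_block:
        g *= float(mg_block_factor(v_mv))
    return SynapseState(a=a, b=b), max(g, 0.0)
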