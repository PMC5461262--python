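"""Built-in voltage-gated channel library.

Reduced Hodgkin–Huxley-style complements covering the dynamical classes of
the cortical patch: transient sodium and delayed-rectifier potassium for
spiking, an M-type potassium current for adaptation in regular-spiking
cells, high-threshold calcium plus Ca-activated potassium for intrinsic
bursting, and a low-threshold (T-type) calcium current for low-threshold
spiking and thalamic cells.  Steady states are Boltzmann sigmoids of the
absolute membrane potential (mV); time constants are deliberately gentle
(≥ 0.5 ms, ten times the 50 µs integration step) so that the explicit
exponential-Euler scheme is well converged at the working step — spikes
are correspondingly broad (~2 ms), which the 5 kHz detection chain
resolves comfortably.

Reversal potentials: E_Na = +50 mV, E_K = −95 mV (ohmic E_Ca ≈ +120 mV).
"""

from __future__ import annotations

from .model_core import ChannelSpec, GateSpec, RateFunction

E_NA_MV = 50.0
E_K_MV = -95.0
E_CA_MV = 120.0

# Transient Na: m²h.  The axonal variant activates ~7 mV more negative
# than the somatic one (as axon-initial-segment sodium channels do), which
# places spike initiation in the axon.
_NA_M = GateSpec(
    name="m", exponent=2,
    inf=RateFunction("sigmoid", A=1.0, V0=-38.0, B=7.0),
    tau=RateFunction("const", A=0.5),
)
_NA_M_AX = GateSpec(
    name="m", exponent=2,
    inf=RateFunction("sigmoid", A=1.0, V0=-45.0, B=7.0),
    tau=RateFunction("const", A=0.5),
)
_NA_H = GateSpec(
    name="h", exponent=1,
    inf=RateFunction("sigmoid", A=1.0, V0=-55.0, B=-7.0),
    tau=RateFunction("const", A=5.0),
)

# Delayed rectifier K: n²
_KDR_N = GateSpec(
    name="n", exponent=2,
    inf=RateFunction("sigmoid", A=1.0, V0=-40.0, B=9.0),
    tau=RateFunction("const", A=2.0),
)

# Persistent Na: small, non-inactivating, activates just below spike
# threshold; provides subthreshold amplification whose gain depends on the
# leak conductance (and hence on membrane damage)
_NAP_M = GateSpec(
    name="m", exponent=1,
    inf=RateFunction("sigmoid", A=1.0, V0=-48.0, B=5.0),
    tau=RateFunction("const", A=2.0),
)

# M-type K (slow, non-inactivating): x_inf/tau form (Yamada-style)
_KM_M = GateSpec(
    name="m", exponent=1,
    inf=RateFunction("sigmoid", A=1.0, V0=-35.0, B=10.0),
    tau=RateFunction("sech", A=1000.0 / 3.3, V0=-35.0, B=20.0),
)

# High-threshold (L-type) Ca: m², fast activation, no inactivation
_CAL_M = GateSpec(
    name="m", exponent=2,
    inf=RateFunction("sigmoid", A=1.0, V0=-20.0, B=9.0),
    tau=RateFunction("const", A=1.5),
)

# Low-threshold (T-type) Ca: m²h with slow de-inactivation
_CAT_M = GateSpec(
    name="m", exponent=2,
    inf=RateFunction("sigmoid", A=1.0, V0=-57.0, B=6.2),
    tau=RateFunction("const", A=1.5),
)
_CAT_H = GateSpec(
    name="h", exponent=1,
    inf=RateFunction("sigmoid", A=1.0, V0=-81.0, B=-4.0),
    tau=RateFunction("const", A=30.0),
)


def na_transient(density: float) -> ChannelSpec:
    """Transient sodium current (spike upstroke), m²h."""
    return ChannelSpec("Na_t", density, E_NA_MV, gates=(_NA_M, _NA_H))


def na_transient_axonal(density: float) -> ChannelSpec:
    """Axonal transient sodium (low-threshold activation), m²h."""
    return ChannelSpec("Na_t_ax", density, E_NA_MV, gates=(_NA_M_AX, _NA_H))


def na_persistent(density: float) -> ChannelSpec:
    """Persistent sodium current (subthreshold amplification), m¹."""
    return ChannelSpec("Na_P", density, E_NA_MV, gates=(_NAP_M,))


def k_delayed_rectifier(density: float) -> ChannelSpec:
    """Delayed-rectifier potassium (repolarisation), n²."""
    return ChannelSpec("K_dr", density, E_K_MV, gates=(_KDR_N,))


def k_m_type(density: float) -> ChannelSpec:
    """M-type slow potassium (spike-frequency adaptation)."""
    return ChannelSpec("K_M", density, E_K_MV, gates=(_KM_M,))


def ca_l_type(density: float) -> ChannelSpec:
    """High-threshold calcium; feeds the calcium pool."""
    return ChannelSpec("Ca_L", density, E_CA_MV, gates=(_CAL_M,), is_calcium=True)


def ca_t_type(density: float) -> ChannelSpec:
    """Low-threshold calcium (rebound/burst); feeds the calcium pool."""
    return ChannelSpec("Ca_T", density, E_CA_MV, gates=(_CAT_M, _CAT_H),
                       is_calcium=True)


def k_ca_dependent(density: float, kd_um: float = 0.5) -> ChannelSpec:
    """Calcium-activated potassium: open fraction Ca/(Ca + kd)."""
    return ChannelSpec("K_Ca", density, E_K_MV, gates=(),
                       ca_dependent=True, ca_kd_um=kd_um)
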