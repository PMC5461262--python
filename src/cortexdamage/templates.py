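"""Desk-scale cell-type templates for the cortical patch.

Fourteen cell types — six excitatory (layer 2/3 regular-spiking and
fast-rhythmic-bursting pyramids, layer 4 spiny stellates, layer 5 tufted
intrinsic-bursting and regular-spiking pyramids, layer 6 non-tufted
pyramids), six cortical interneurons (superficial and deep basket,
axo-axonic and low-threshold-spiking cells) and two thalamic types
(reticular and thalamocortical relay) — mapped onto five dynamical classes:

==========================  =========================================
class                       channel complement (soma / axon hillock)
==========================  =========================================
regular spiking (RS)        Na_t, K_dr, K_M
fast spiking (FS)           Na_t, K_dr
intrinsic bursting (IB)     Na_t, K_dr, K_M, Ca_L, K_Ca
low-threshold spiking (LTS) Na_t, K_dr, Ca_T
thalamic (TC/nRT)           Na_t, K_dr, Ca_T
==========================  =========================================

The fast-rhythmic-bursting pyramid is labelled distinctly but reuses the
RS kinetics.  Templates use 7–10 compartments (soma, axon initial segment,
axon, basal/apical/distal dendrites); the anatomical class labels are what
the damage model targets, so partial-damage experiments transfer unchanged
to finer morphologies supplied via configuration.

Axonal membrane is modelled leakier than somatodendritic membrane
(specific Rm 0.1 vs 1.0 Ω·m²), concentrating baseline leak — and hence
the absolute conductance added by fractional Rm damage — near the spike
initiation zone.
"""

from __future__ import annotations

import json
from importlib import resources

from . import channels as ch
from .model_core import CompartmentClass, CompartmentParams, NeuronTemplate

# passive parameters
RM_SOMA_DEND = 1.0        # Ω·m²
RM_AXON = 0.05            # Ω·m² (leaky unmyelinated axon)
CM = 0.01                 # F/m²  (1 µF/cm²)
RA = 3.0                  # Ω·m   (300 Ω·cm)
E_LEAK_MV = -70.0

# channel densities, S/m² — the spike machinery is concentrated in the
# axon initial segment and axon proper; the soma carries enough transient
# Na to regenerate the back-propagated spike above the detection threshold
# plus a persistent-Na amplifier of subthreshold synaptic input
_D = {
    "ais_na": 800.0, "ais_kdr": 1200.0,
    "ax_na": 400.0, "ax_kdr": 600.0,
    "soma_na": 600.0, "soma_kdr": 400.0, "soma_nap": 6.0,
    "km": 8.0, "cal": 10.0, "kca": 50.0, "cat": 15.0,
}

CC = CompartmentClass


def _comp(cid, parent, length, diam, cls, offset, rm):
    return CompartmentParams(
        id=cid, parent_id=parent, length_um=length, diameter_um=diam,
        specific_rm=rm, specific_cm=CM, specific_ra=RA,
        leak_reversal_mv=E_LEAK_MV, compartment_class=cls, offset_um=offset)


def _pyramidal_compartments() -> list[CompartmentParams]:
    """10-compartment pyramid: apical trunk toward the pia (−z).

    Neurite diameters and the 300 Ω·cm axial resistivity keep every
    compartment-to-compartment coupling time constant well above the 50 µs
    step, so the explicit integration of the cable terms stays converged.
    """
    return [
        _comp(0, None, 20, 20, CC.SOMA, (0, 0, 0), RM_SOMA_DEND),
        _comp(1, 0, 50, 1.0, CC.AXON_INITIAL_SEGMENT, (0, 0, 35), RM_AXON),
        _comp(2, 1, 100, 1.0, CC.AXON, (0, 0, 110), RM_AXON),
        _comp(3, 2, 100, 1.0, CC.AXON, (0, 0, 210), RM_AXON),
        _comp(4, 0, 150, 1.2, CC.BASAL_DENDRITE, (75, 0, 30), RM_SOMA_DEND),
        _comp(5, 0, 150, 1.2, CC.BASAL_DENDRITE, (-75, 0, 30), RM_SOMA_DEND),
        _comp(6, 0, 200, 1.5, CC.APICAL_DENDRITE, (0, 0, -110), RM_SOMA_DEND),
        _comp(7, 6, 200, 1.2, CC.APICAL_DENDRITE, (0, 0, -310), RM_SOMA_DEND),
        _comp(8, 7, 200, 1.0, CC.DISTAL_DENDRITE, (0, 0, -510), RM_SOMA_DEND),
        _comp(9, 6, 150, 1.2, CC.APICAL_DENDRITE, (60, 0, -180), RM_SOMA_DEND),
    ]


def _stellate_compartments() -> list[CompartmentParams]:
    """8-compartment multipolar cell (stellates, interneurons, thalamic).

    Two of the dendrites are 300 µm two-segment chains so every cell type
    offers synaptic sites at a comparable electrotonic depth (~1 length
    constant) from the soma.
    """
    return [
        _comp(0, None, 16, 16, CC.SOMA, (0, 0, 0), RM_SOMA_DEND),
        _comp(1, 0, 50, 1.0, CC.AXON_INITIAL_SEGMENT, (0, 0, 35), RM_AXON),
        _comp(2, 1, 100, 1.0, CC.AXON, (0, 0, 110), RM_AXON),
        _comp(3, 0, 150, 1.0, CC.BASAL_DENDRITE, (80, 0, -20), RM_SOMA_DEND),
        _comp(4, 3, 150, 0.8, CC.DISTAL_DENDRITE, (230, 0, -40), RM_SOMA_DEND),
        _comp(5, 0, 150, 1.0, CC.BASAL_DENDRITE, (-80, 0, 20), RM_SOMA_DEND),
        _comp(6, 5, 150, 0.8, CC.DISTAL_DENDRITE, (-230, 0, 40), RM_SOMA_DEND),
        _comp(7, 0, 150, 1.0, CC.BASAL_DENDRITE, (0, 80, 0), RM_SOMA_DEND),
    ]


def _active(extra_soma=()):
    """Channel map: hot axon initial segment and axon, moderate soma,
    passive dendrites."""
    return {
        CC.AXON_INITIAL_SEGMENT: [
            ch.na_transient_axonal(_D["ais_na"]), ch.k_delayed_rectifier(_D["ais_kdr"])],
        CC.AXON: [
            ch.na_transient_axonal(_D["ax_na"]), ch.k_delayed_rectifier(_D["ax_kdr"])],
        CC.SOMA: [
            ch.na_transient(_D["soma_na"]), ch.k_delayed_rectifier(_D["soma_kdr"]),
            ch.na_persistent(_D["soma_nap"]), *extra_soma],
    }


def _rs_channels():
    return _active([ch.k_m_type(_D["km"])])


def _fs_channels():
    return _active()


def _ib_channels():
    return _active([ch.k_m_type(_D["km"]), ch.ca_l_type(_D["cal"]),
                    ch.k_ca_dependent(_D["kca"])])


def _lts_channels():
    return _active([ch.ca_t_type(_D["cat"])])


_TYPE_DEFS = [
    # (type_name, morphology, channel factory)
    ("L23_RS_pyramid", _pyramidal_compartments, _rs_channels),
    ("L23_FRB_pyramid", _pyramidal_compartments, _rs_channels),
    ("L4_spiny_stellate", _stellate_compartments, _rs_channels),
    ("L5_IB_tufted_pyramid", _pyramidal_compartments, _ib_channels),
    ("L5_RS_tufted_pyramid", _pyramidal_compartments, _rs_channels),
    ("L6_nontufted_pyramid", _pyramidal_compartments, _rs_channels),
    ("L23_basket", _stellate_compartments, _fs_channels),
    ("L23_axoaxonic", _stellate_compartments, _fs_channels),
    ("L23_LTS", _stellate_compartments, _lts_channels),
    ("L5_basket", _stellate_compartments, _fs_channels),
    ("L5_axoaxonic", _stellate_compartments, _fs_channels),
    ("L5_LTS", _stellate_compartments, _lts_channels),
    ("nRT", _stellate_compartments, _lts_channels),
    ("TCR", _stellate_compartments, _lts_channels),
]

TYPE_NAMES = [t[0] for t in _TYPE_DEFS]


def build_templates() -> dict[str, NeuronTemplate]:
    """Construct the 14 templates programmatically (source of truth)."""
    out = {}
    for name, morph, chans in _TYPE_DEFS:
        out[name] = NeuronTemplate(
            type_name=name, compartments=morph(), channels=chans(),
            spike_source=0, spike_threshold_mv=0.0, refractory_ms=2.0)
    return out


def templates_to_json() -> str:
    """Serialise the registry to the shipped package-data format.

    Types that share morphology and channel complement (differing only in
    their name) are stored once and referenced with ``{"like": <name>}``.
    """
    reg = build_templates()
    out: dict[str, dict] = {}
    canonical: dict[str, str] = {}     # structure signature → first type name
    for name, tpl in reg.items():
        d = tpl.to_dict()
        d.pop("type_name")
        sig = json.dumps(d, sort_keys=True)
        if sig in canonical:
            out[name] = {"like": canonical[sig]}
        else:
            canonical[sig] = name
            out[name] = d
    return json.dumps(out, separators=(",", ":"))


def load_templates() -> dict[str, NeuronTemplate]:
    """Load the registry from the shipped JSON package data."""
    text = resources.files("cortexdamage").joinpath("data/templates.json").read_text()
    raw = json.loads(text)
    out: dict[str, NeuronTemplate] = {}
    for name, d in raw.items():
        if "like" in d:
            d = dict(raw[d["like"]])
        d = {**d, "type_name": name}
        out[name] = NeuronTemplate.from_dict(d)
    return out
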