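"""Membrane-pore damage as a scalar reduction of membrane resistance.

Blast-induced pore formation is operationalised as a uniform fractional
drop in specific membrane resistance: damage level d maps every targeted
compartment's Rm to (1 − d)·Rm — equivalently the leak conductance scales
by 1/(1 − d) — applied at the same level simultaneously across all
simulated neurons (thalamic cells included).  The leak reversal is
untouched, so the resting potential is unchanged; what changes is how
strongly the membrane shunts synaptic and spike currents.

Damage may target the whole cell, the axons alone (axon proper plus axon
initial segment), or the somatic and dendritic compartments; the two
partial locations partition the whole-cell set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .model_core import (AXONAL_CLASSES, SOMATODENDRITIC_CLASSES,
                         CompartmentClass, ConfigurationError, NeuronTemplate)
from .network_builder import Network

LOCATIONS = ("whole_cell", "axons", "soma_and_dendrites")


class AlreadyDamagedError(RuntimeError):
    """Damage may only be applied once, from the undamaged baseline."""


@dataclass(frozen=True)
class DamageSpec:
    """Damage level (fraction of Rm removed) and membrane location."""

    level: float
    location: str = "whole_cell"

    def __post_init__(self):
        if not (0.0 <= self.level < 1.0):
            raise ConfigurationError("damage level must be in [0, 1)")
        if self.location not in LOCATIONS:
            raise ConfigurationError(
                f"location must be one of {LOCATIONS}, got {self.location!r}")


def rm_multiplier(level: float) -> float:
    """Rm scale factor for a damage level: 10% damage → Rm at 90% of baseline."""
    if not (0.0 <= level < 1.0):
        raise ConfigurationError("damage level must be in [0, 1)")
    return 1.0 - level


def select_compartments(template: NeuronTemplate, location: str) -> set[int]:
    """Compartment ids targeted by a damage location on one template."""
    if location == "whole_cell":
        classes = AXONAL_CLASSES | SOMATODENDRITIC_CLASSES
    elif location == "axons":
        classes = AXONAL_CLASSES
    elif location == "soma_and_dendrites":
        classes = SOMATODENDRITIC_CLASSES
    else:
        raise ConfigurationError(f"unknown damage location {location!r}")
    ids = {c.id for c in template.compartments if c.compartment_class in classes}
    if not ids:
        warnings.warn(
            f"{template.type_name}: no compartments of location {location!r}",
            stacklevel=2)
    return ids


def apply_damage(network: Network, spec: DamageSpec) -> Network:
    """Return a damaged copy of a baseline network.

    Every targeted compartment of every template has specific_rm scaled by
    rm_multiplier(level); everything else (geometry, channels, wiring,
    drive) is shared/untouched.  Refuses to compound damage.
    """
    if network.damage is not None:
        raise AlreadyDamagedError(
            "network already carries damage; rebuild the baseline first")
    mult = rm_multiplier(spec.level)
    new_templates = {}
    for name, tpl in network.templates.items():
        targeted = select_compartments(tpl, spec.location)
        comps = [
            replace(c, specific_rm=c.specific_rm * mult) if c.id in targeted else c
            for c in tpl.compartments
        ]
        new_templates[name] = NeuronTemplate(
            type_name=tpl.type_name, compartments=comps, channels=tpl.channels,
            spike_source=tpl.spike_source,
            spike_threshold_mv=tpl.spike_threshold_mv,
            refractory_ms=tpl.refractory_ms)
    return Network(config=network.config, templates=new_templates,
                   positions=network.positions, connections=network.connections,
                   drive=network.drive, damage=spec)
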