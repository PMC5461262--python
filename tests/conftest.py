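"""Shared fixtures: desk-scale simulations are expensive, so the damage
grid is simulated once per session and reused by every test that asserts
rate orderings."""

from __future__ import annotations

import numpy as np
import pytest

from cortexdamage.damage_model import DamageSpec, apply_damage
from cortexdamage.engine import Simulation
from cortexdamage.network_builder import build_network, desk_scale_config

GRID_SEED = 1234
GRID_DURATION_S = 5.0
GRID_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
GRID_LOCATIONS = ("whole_cell", "axons", "soma_and_dendrites")


@pytest.fixture(scope="session")
def damage_grid_rates() -> dict[str, list[float]]:
    """Aggregate firing rate (APs/s, simulator events) for every
    (location, level) cell of the desk-scale damage grid at a fixed seed."""
    cfg = desk_scale_config(seed=GRID_SEED)
    out: dict[str, list[float]] = {}
    baseline = None
    for loc in GRID_LOCATIONS:
        rates = []
        for level in GRID_LEVELS:
            if level == 0.0:
                if baseline is None:
                    net = build_network(cfg)
                    rec = Simulation(net).run(GRID_DURATION_S, record_soma=False)
                    baseline = len(rec.spikes) / GRID_DURATION_S
                rates.append(baseline)
                continue
            net = apply_damage(build_network(cfg), DamageSpec(level, loc))
            rec = Simulation(net).run(GRID_DURATION_S, record_soma=False)
            rates.append(len(rec.spikes) / GRID_DURATION_S)
        out[loc] = rates
    return out


@pytest.fixture(scope="session")
def single_rs_cell_run():
    """A tonically firing single regular-spiking pyramid (5 s, 0.2 nA)."""
    from cortexdamage.network_builder import single_cell_network

    net = single_cell_network("L23_RS_pyramid")
    sim = Simulation(net)
    sim.inject_current(0, 0, 0.2e-9)
    rec = sim.run(5.0)
    return rec
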