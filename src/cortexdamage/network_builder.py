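"""Construction of the layered cortical patch.

The patch is a 150 µm × 150 µm × 2,871 µm block of cortex (plus a thalamic
block beneath it) populated by microcolumns of 23 or 24 neurons, each
containing every one of the 14 cell types.  Somas are placed uniformly at
random inside their type's layer band and their column's footprint;
connections are realised independently per ordered neuron pair with
type-pair probabilities, weighted u·exp(−r/λ_w) with u ~ U(0,1], and given
conduction delays proportional to distance (1 s/m).  Background drive is a
per-step Bernoulli EPSP train (rate λ per 50 µs step) delivered to a
random 10% of the population.

All randomness flows from the configuration seed through three
independent, salted streams (placement, connectivity, drive), so a given
seed reproduces the network byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import CompartmentClass, ConfigurationError, NeuronTemplate, SynapseSpec
from .templates import TYPE_NAMES, build_templates

PATCH_DEPTH_UM = 2871.0
COLUMN_PITCH_UM = 30.0
THALAMUS_THICKNESS_UM = 300.0

# fraction-of-depth layer boundaries (L1 carries no somas in this registry)
LAYER_BOUNDS = {
    "L1": (0.00, 0.10),
    "L2/3": (0.10, 0.35),
    "L4": (0.35, 0.50),
    "L5": (0.50, 0.75),
    "L6": (0.75, 1.00),
}


@dataclass(frozen=True)
class LayerSpec:
    name: str
    z_min_um: float
    z_max_um: float

    def __post_init__(self):
        if not (self.z_min_um < self.z_max_um):
            raise ConfigurationError(f"layer {self.name}: empty z band")


def cortical_layers() -> dict[str, LayerSpec]:
    layers = {
        name: LayerSpec(name, lo * PATCH_DEPTH_UM, hi * PATCH_DEPTH_UM)
        for name, (lo, hi) in LAYER_BOUNDS.items()
    }
    layers["thalamus"] = LayerSpec(
        "thalamus", PATCH_DEPTH_UM, PATCH_DEPTH_UM + THALAMUS_THICKNESS_UM)
    return layers


@dataclass(frozen=True)
class CellTypeSpec:
    type_name: str
    layer: str
    count_per_microcolumn: int
    excitatory: bool
    target_classes: tuple[CompartmentClass, ...]
    axo_axonic: bool = False
    thalamocortical: bool = False


_DENDRITES = (CompartmentClass.BASAL_DENDRITE, CompartmentClass.APICAL_DENDRITE,
              CompartmentClass.DISTAL_DENDRITE)


def default_cell_registry() -> dict[str, CellTypeSpec]:
    """The 14-type registry; base counts sum to 23 per microcolumn.

    24-neuron columns carry one extra L2/3 regular-spiking pyramid.
    """
    defs = [
        # name,               layer,     n, exc,  targets
        ("L23_RS_pyramid", "L2/3", 4, True, _DENDRITES),
        ("L23_FRB_pyramid", "L2/3", 2, True, _DENDRITES),
        ("L4_spiny_stellate", "L4", 3, True, _DENDRITES),
        ("L5_IB_tufted_pyramid", "L5", 2, True, _DENDRITES),
        ("L5_RS_tufted_pyramid", "L5", 2, True, _DENDRITES),
        ("L6_nontufted_pyramid", "L6", 2, True, _DENDRITES),
        ("L23_basket", "L2/3", 1, False, (CompartmentClass.SOMA,)),
        ("L23_axoaxonic", "L2/3", 1, False, (CompartmentClass.AXON_INITIAL_SEGMENT,)),
        ("L23_LTS", "L2/3", 1, False, _DENDRITES),
        ("L5_basket", "L5", 1, False, (CompartmentClass.SOMA,)),
        ("L5_axoaxonic", "L5", 1, False, (CompartmentClass.AXON_INITIAL_SEGMENT,)),
        ("L5_LTS", "L5", 1, False, _DENDRITES),
        ("nRT", "thalamus", 1, False, _DENDRITES),
        ("TCR", "thalamus", 1, True, _DENDRITES),
    ]
    reg = {}
    for name, layer, n, exc, targets in defs:
        reg[name] = CellTypeSpec(
            type_name=name, layer=layer, count_per_microcolumn=n,
            excitatory=exc, target_classes=tuple(targets),
            axo_axonic="axoaxonic" in name, thalamocortical=(name == "TCR"))
    assert set(reg) == set(TYPE_NAMES)
    return reg


# the type receiving one extra cell in 24-neuron columns
PLUS_ONE_TYPE = "L23_RS_pyramid"
# repeating column-size pattern; 25 columns → 15×23 + 10×24 = 585 neurons
_COLUMN_PATTERN = (23, 24, 23, 24, 23)

# types whose axon initial segments receive full axo-axonic innervation
AXO_AXONIC_TARGET_TYPES = (
    "L23_RS_pyramid", "L23_FRB_pyramid", "L5_IB_tufted_pyramid",
    "L5_RS_tufted_pyramid", "L6_nontufted_pyramid", "L4_spiny_stellate")


def column_size(column_index: int) -> int:
    return _COLUMN_PATTERN[column_index % len(_COLUMN_PATTERN)]


def default_probability(pre: CellTypeSpec, post: CellTypeSpec) -> float:
    """Documented default type-pair connection probabilities (all in [0.01, 0.25]).

    Axo-axonic presynaptic cells are handled by the deterministic
    full-connectivity rule, not by this matrix.
    """
    if pre.axo_axonic:
        return 0.0
    if pre.thalamocortical and post.layer in ("L4", "L6"):
        return 0.15
    if pre.excitatory and post.excitatory:
        return 0.10
    if pre.excitatory and not post.excitatory:
        return 0.20
    if not pre.excitatory and post.excitatory:
        return 0.25
    return 0.05


# synaptic kinetic templates; peak conductances are configuration
def ampa_spec(gmax: float) -> SynapseSpec:
    return SynapseSpec("AMPA", gmax, rise_tau_ms=0.5, decay_tau_ms=3.0, reversal_mv=0.0)


def nmda_spec(gmax: float) -> SynapseSpec:
    return SynapseSpec("NMDA", gmax, rise_tau_ms=5.0, decay_tau_ms=75.0,
                       reversal_mv=0.0, mg_block=True)


def gaba_a_spec(gmax: float) -> SynapseSpec:
    return SynapseSpec("GABA_A", gmax, rise_tau_ms=0.5, decay_tau_ms=7.0,
                       reversal_mv=-75.0)


@dataclass
class NetworkConfig:
    """Everything needed to build and run one network realisation."""

    n_microcolumns: int
    seed: int = 1234
    duration_s: float = 20.0
    dt_us: float = 50.0
    drive_fraction: float = 0.10
    drive_rate_per_step: float = 0.005
    weight_decay_um: float = 100.0
    conduction_velocity_m_s: float = 1.0
    # peak synaptic conductances (S); drive values set by the calibration run
    ampa_gmax_s: float = 1.5e-9
    nmda_gmax_s: float = 0.3e-9
    gaba_gmax_s: float = 3.0e-9
    drive_gmax_s: float = 10.0e-9
    drive_nmda_gmax_s: float = 0.0      # optional slow drive component, off
    probability_overrides: dict = field(default_factory=dict)
    registry: dict[str, CellTypeSpec] = field(default_factory=default_cell_registry)

    def __post_init__(self):
        if self.n_microcolumns < 1:
            raise ConfigurationError("need at least one microcolumn")
        if not (0.0 <= self.drive_fraction <= 1.0):
            raise ConfigurationError("drive fraction must be in [0, 1]")
        if self.dt_us <= 0:
            raise ConfigurationError("dt must be positive")

    @property
    def dt_s(self) -> float:
        return self.dt_us * 1e-6

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    @property
    def grid_side(self) -> int:
        return math.ceil(math.sqrt(self.n_microcolumns))

    @property
    def patch_xy_um(self) -> float:
        return self.grid_side * COLUMN_PITCH_UM

    @property
    def n_neurons(self) -> int:
        return sum(column_size(i) for i in range(self.n_microcolumns))

    def probability(self, pre: CellTypeSpec, post: CellTypeSpec) -> float:
        key = (pre.type_name, post.type_name)
        if key in self.probability_overrides:
            return float(self.probability_overrides[key])
        return default_probability(pre, post)


def full_scale_config(seed: int = 1234, **kw) -> NetworkConfig:
    """25 microcolumns (15×23 + 10×24) — the 585-neuron patch."""
    return NetworkConfig(n_microcolumns=25, seed=seed, **kw)


def desk_scale_config(n_microcolumns: int = 2, seed: int = 1234, **kw) -> NetworkConfig:
    """Reduced patch for desk-scale experiments (default 2 columns, 47 neurons)."""
    return NetworkConfig(n_microcolumns=n_microcolumns, seed=seed, **kw)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(salt)]))


def place_neurons(config: NetworkConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Place every soma: uniform in the column footprint and the layer band.

    Returns a frame with one row per neuron: neuron_id, type_name,
    microcolumn, x/y/z_um.  Deterministic given the seed.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 0)
    layers = cortical_layers()
    rows = []
    nid = 0
    for col in range(config.n_microcolumns):
        gx, gy = col % config.grid_side, col // config.grid_side
        x0, y0 = gx * COLUMN_PITCH_UM, gy * COLUMN_PITCH_UM
        for spec in config.registry.values():
            n = spec.count_per_microcolumn
            if column_size(col) == 24 and spec.type_name == PLUS_ONE_TYPE:
                n += 1
            band = layers[spec.layer]
            # keep a margin so short template neurites stay near the band
            margin = min(20.0, 0.1 * (band.z_max_um - band.z_min_um))
            for _ in range(n):
                x = x0 + rng.uniform(0.0, COLUMN_PITCH_UM)
                y = y0 + rng.uniform(0.0, COLUMN_PITCH_UM)
                z = rng.uniform(band.z_min_um + margin, band.z_max_um - margin)
                rows.append((nid, spec.type_name, col, x, y, z))
                nid += 1
    df = pd.DataFrame(rows, columns=["neuron_id", "type_name", "microcolumn",
                                     "x_um", "y_um", "z_um"])
    return df


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def assign_delay(distance_um, velocity_m_s: float = 1.0):
    """Conduction delay in ms for a soma→target distance (1 s/m default)."""
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    return d * 1e-3 / velocity_m_s      # µm → mm, 1 ms per mm at 1 m/s


def _target_compartments(template: NeuronTemplate,
                         classes: tuple[CompartmentClass, ...]) -> list[int]:
    ids = [c.id for c in template.compartments if c.compartment_class in classes]
    if ids:
        return ids
    # fall back to any dendrite, then the soma, so every pairing is wirable
    ids = [c.id for c in template.compartments
           if c.compartment_class in _DENDRITES]
    return ids or [template.compartments[0].id]


def build_connections(config: NetworkConfig, positions: pd.DataFrame,
                      seed: Optional[int] = None,
                      templates: Optional[dict[str, NeuronTemplate]] = None,
                      ) -> pd.DataFrame:
    """Realise the random connection table plus the axo-axonic rule.

    Excitatory presynaptic neurons contribute an AMPA and an NMDA row per
    realised connection (shared weight and compartment); inhibitory neurons
    contribute a single GABA_A row.  Weight = u·exp(−r/λ_w), u ~ U(0,1].
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    templates = templates or build_templates()
    reg = config.registry

    pos = positions.set_index("neuron_id")
    soma_xyz = pos[["x_um", "y_um", "z_um"]].to_numpy()
    type_of = pos["type_name"].to_numpy()
    ids_by_type = {t: pos.index[type_of == t].to_numpy() for t in reg}

    comp_offsets = {
        t: {c.id: np.asarray(c.offset_um, dtype=float)
            for c in templates[t].compartments}
        for t in reg
    }

    pre_l, post_l, comp_l, kind_l, w_l, d_l = [], [], [], [], [], []

    def emit(pre_ids, post_ids, comp_ids, excitatory):
        tgt = soma_xyz[post_ids].copy()
        for k, (pid, cid) in enumerate(zip(post_ids, comp_ids)):
            tgt[k] += comp_offsets[type_of[pid]][cid]
        r = np.linalg.norm(tgt - soma_xyz[pre_ids], axis=1)
        u = 1.0 - rng.random(len(pre_ids))          # U(0, 1]
        w = u * np.exp(-r / config.weight_decay_um)
        delay = assign_delay(r, config.conduction_velocity_m_s)
        kinds = ["AMPA", "NMDA"] if excitatory else ["GABA_A"]
        for kind in kinds:
            pre_l.append(pre_ids)
            post_l.append(post_ids)
            comp_l.append(np.asarray(comp_ids))
            kind_l.append(np.full(len(pre_ids), kind, dtype=object))
            w_l.append(w)
            d_l.append(delay)

    for pre_t, pre_spec in reg.items():
        pre_ids_all = ids_by_type[pre_t]
        if len(pre_ids_all) == 0:
            continue
        if pre_spec.axo_axonic:
            # deterministic rule: every axo-axonic cell contacts the axon
            # initial segment of every pyramidal / L4 stellate cell
            for post_t in AXO_AXONIC_TARGET_TYPES:
                post_ids_all = ids_by_type[post_t]
                if len(post_ids_all) == 0:
                    continue
                ais = [c.id for c in templates[post_t].compartments
                       if c.compartment_class is CompartmentClass.AXON_INITIAL_SEGMENT][0]
                pre_g, post_g = np.meshgrid(pre_ids_all, post_ids_all, indexing="ij")
                pre_f, post_f = pre_g.ravel(), post_g.ravel()
                emit(pre_f, post_f, np.full(len(pre_f), ais), excitatory=False)
            continue
        for post_t, post_spec in reg.items():
            p = config.probability(pre_spec, post_spec)
            post_ids_all = ids_by_type[post_t]
            if p <= 0 or len(post_ids_all) == 0:
                continue
            mask = rng.random((len(pre_ids_all), len(post_ids_all))) < p
            if pre_t == post_t:
                np.fill_diagonal(mask, False)       # no self-connections
            pi, qi = np.nonzero(mask)
            if len(pi) == 0:
                continue
            pre_f, post_f = pre_ids_all[pi], post_ids_all[qi]
            cands = _target_compartments(templates[post_t], pre_spec.target_classes)
            comp_f = rng.choice(cands, size=len(pre_f))
            emit(pre_f, post_f, comp_f, excitatory=pre_spec.excitatory)

    if not pre_l:
        return pd.DataFrame(columns=["pre_id", "post_id", "post_compartment",
                                     "kind", "weight", "delay_ms"])
    df = pd.DataFrame({
        "pre_id": np.concatenate(pre_l).astype(int),
        "post_id": np.concatenate(post_l).astype(int),
        "post_compartment": np.concatenate(comp_l).astype(int),
        "kind": np.concatenate(kind_l),
        "weight": np.concatenate(w_l),
        "delay_ms": np.concatenate(d_l),
    })
    return df.sort_values(["pre_id", "post_id", "post_compartment", "kind"],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# drive
# ---------------------------------------------------------------------------

@dataclass
class DriveSpec:
    """Poisson background EPSP drive to 10% of the population.

    Events land on a distal dendritic compartment of each driven neuron
    (``target_compartments``, one id per driven neuron), so the somatic
    impact of each EPSP carries the dendrite-to-soma electrotonic transfer
    — the component of synaptic efficacy most sensitive to membrane-
    resistance damage.
    """

    driven_ids: np.ndarray              # neuron ids
    event_steps: list[np.ndarray]       # per driven neuron, sorted step indices
    synapse: SynapseSpec
    nmda_synapse: Optional[SynapseSpec] = None   # slow co-activated component
    target_compartments: Optional[np.ndarray] = None   # per driven neuron
    target_compartment: int = 0         # fallback when no per-neuron ids

    def target_of(self, k: int) -> int:
        if self.target_compartments is not None:
            return int(self.target_compartments[k])
        return self.target_compartment

    @property
    def n_events(self) -> int:
        return int(sum(len(e) for e in self.event_steps))


DRIVE_TARGET_DEPTH_UM = 300.0


def distal_dendrite_id(template: NeuronTemplate) -> int:
    """Dendritic compartment closest to the nominal drive depth (~300 µm).

    Delivering the background EPSPs at a fixed electrotonic depth makes
    their somatic efficacy comparable across morphologies.
    """
    dend = [c for c in template.compartments if c.compartment_class in _DENDRITES]
    if not dend:
        return template.compartments[0].id
    return min(dend, key=lambda c: abs(
        float(np.linalg.norm(c.offset_um)) - DRIVE_TARGET_DEPTH_UM)).id


def build_drive(config: NetworkConfig, seed: Optional[int] = None,
                n_neurons: Optional[int] = None,
                positions: Optional[pd.DataFrame] = None,
                templates: Optional[dict[str, NeuronTemplate]] = None) -> DriveSpec:
    """Select round(0.10·N) neurons; per step Bernoulli(λ) event trains."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 2)
    n = config.n_neurons if n_neurons is None else n_neurons
    n_driven = int(round(config.drive_fraction * n))
    driven = np.sort(rng.choice(n, size=n_driven, replace=False))
    lam = config.drive_rate_per_step
    steps = config.n_steps
    events = []
    for _ in range(n_driven):
        if lam <= 0:
            events.append(np.empty(0, dtype=np.int64))
            continue
        # geometric inter-event gaps ≡ per-step Bernoulli(λ), far cheaper
        count_guess = int(lam * steps + 6 * math.sqrt(lam * steps)) + 10
        gaps = rng.geometric(lam, size=count_guess)
        t = np.cumsum(gaps) - 1
        while len(t) == 0 or t[-1] < steps:
            gaps = rng.geometric(lam, size=count_guess)
            t = np.append(t, (t[-1] + 1 if len(t) else 0) + np.cumsum(gaps) - 1)
        events.append(t[t < steps].astype(np.int64))
    targets = None
    if positions is not None:
        templates = templates or build_templates()
        type_of = positions.set_index("neuron_id")["type_name"]
        targets = np.array([distal_dendrite_id(templates[type_of[int(i)]])
                            for i in driven], dtype=np.int64)
    nmda = (nmda_spec(config.drive_nmda_gmax_s)
            if config.drive_nmda_gmax_s > 0 else None)
    return DriveSpec(driven_ids=driven, event_steps=events,
                     synapse=ampa_spec(config.drive_gmax_s), nmda_synapse=nmda,
                     target_compartments=targets)


# ---------------------------------------------------------------------------
# assembled network
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A fully realised network: placement + wiring + drive + templates."""

    config: NetworkConfig
    templates: dict[str, NeuronTemplate]
    positions: pd.DataFrame
    connections: pd.DataFrame
    drive: DriveSpec
    damage: Optional[object] = None     # DamageSpec once applied

    @property
    def n_neurons(self) -> int:
        return len(self.positions)


def single_cell_network(type_name: str, seed: int = 0,
                        template: Optional[NeuronTemplate] = None,
                        **config_kw) -> Network:
    """One isolated neuron of a given type: no wiring, no drive.

    Used for current-injection characterisation and calibration.
    """
    config = NetworkConfig(n_microcolumns=1, seed=seed, **config_kw)
    templates = build_templates()
    if template is not None:
        templates = dict(templates)
        templates[type_name] = template
    positions = pd.DataFrame(
        [(0, type_name, 0, 15.0, 15.0, 1000.0)],
        columns=["neuron_id", "type_name", "microcolumn", "x_um", "y_um", "z_um"])
    connections = pd.DataFrame(columns=["pre_id", "post_id", "post_compartment",
                                        "kind", "weight", "delay_ms"])
    drive = DriveSpec(driven_ids=np.empty(0, dtype=np.int64), event_steps=[],
                      synapse=ampa_spec(config.drive_gmax_s))
    return Network(config=config, templates=templates, positions=positions,
                   connections=connections, drive=drive)


def build_network(config: NetworkConfig,
                  templates: Optional[dict[str, NeuronTemplate]] = None) -> Network:
    """Place, wire and drive a network from a configuration (seeded)."""
    templates = templates or build_templates()
    positions = place_neurons(config)
    connections = build_connections(config, positions, templates=templates)
    drive = build_drive(config, n_neurons=len(positions), positions=positions,
                        templates=templates)
    return Network(config=config, templates=templates, positions=positions,
                   connections=connections, drive=drive)
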