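"""Patch construction: composition, placement, wiring, delays, drive."""

import numpy as np
import pandas as pd
import pytest

from cortexdamage.model_core import CompartmentClass, ConfigurationError
from cortexdamage.network_builder import (
    AXO_AXONIC_TARGET_TYPES, assign_delay, build_connections, build_drive,
    build_network, cortical_layers, default_cell_registry, desk_scale_config,
    full_scale_config, place_neurons,
)
from cortexdamage.templates import TYPE_NAMES, build_templates


class TestConfiguration:
    def test_full_scale_counts_585_neurons(self):
        assert full_scale_config().n_neurons == 585

    def test_desk_scale_two_columns_has_47_neurons(self):
        assert desk_scale_config(2).n_neurons == 47

    def test_single_column_has_all_14_types(self):
        cfg = desk_scale_config(1)
        assert cfg.n_neurons in (23, 24)
        pos = place_neurons(cfg)
        assert set(pos["type_name"]) == set(TYPE_NAMES)

    def test_registry_has_exactly_14_types(self):
        assert len(default_cell_registry()) == 14
        assert len(TYPE_NAMES) == 14

    def test_zero_columns_rejected(self):
        with pytest.raises(ConfigurationError):
            desk_scale_config(0)


class TestPlacement:
    def test_full_scale_somas_inside_patch_and_layers(self):
        cfg = full_scale_config(seed=3)
        pos = place_neurons(cfg)
        assert len(pos) == 585
        assert (pos["x_um"] >= 0).all() and (pos["x_um"] <= 150).all()
        assert (pos["y_um"] >= 0).all() and (pos["y_um"] <= 150).all()
        layers = cortical_layers()
        reg = cfg.registry
        for _, row in pos.iterrows():
            band = layers[reg[row["type_name"]].layer]
            assert band.z_min_um <= row["z_um"] <= band.z_max_um

    def test_every_microcolumn_contains_every_type(self):
        pos = place_neurons(full_scale_config(seed=5))
        per_col = pos.groupby("microcolumn")["type_name"].agg(set)
        assert all(types == set(TYPE_NAMES) for types in per_col)

    def test_same_seed_reproduces_coordinates(self):
        cfg = desk_scale_config(seed=11)
        pd.testing.assert_frame_equal(place_neurons(cfg), place_neurons(cfg))


class TestDelays:
    @pytest.mark.parametrize("dist_um,expected_ms",
                             [(0.0, 0.0), (1000.0, 1.0), (2871.0, 2.871)])
    def test_one_second_per_meter(self, dist_um, expected_ms):
        assert assign_delay(dist_um) == pytest.approx(expected_ms)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            assign_delay(-1.0)


class TestConnections:
    def test_zero_probability_leaves_only_axoaxonic_rows(self):
        cfg = desk_scale_config(seed=2)
        reg = cfg.registry
        cfg.probability_overrides = {
            (a, b): 0.0 for a in reg for b in reg}
        pos = place_neurons(cfg)
        conn = build_connections(cfg, pos)
        # full-connectivity rule only: every axo-axonic cell onto every
        # pyramidal / spiny-stellate axon initial segment
        n_aa = pos["type_name"].str.contains("axoaxonic").sum()
        n_tgt = pos["type_name"].isin(AXO_AXONIC_TARGET_TYPES).sum()
        assert len(conn) == n_aa * n_tgt
        assert (conn["kind"] == "GABA_A").all()
        tpl = build_templates()
        ais = {t: [c.id for c in tpl[t].compartments
                   if c.compartment_class is CompartmentClass.AXON_INITIAL_SEGMENT][0]
               for t in AXO_AXONIC_TARGET_TYPES}
        type_of = pos.set_index("neuron_id")["type_name"]
        for _, r in conn.iterrows():
            assert r["post_compartment"] == ais[type_of[r["post_id"]]]

    def test_synapse_kind_follows_presynaptic_class(self):
        cfg = desk_scale_config(seed=4)
        pos = place_neurons(cfg)
        conn = build_connections(cfg, pos)
        reg = cfg.registry
        exc = {t for t, s in reg.items() if s.excitatory}
        type_of = pos.set_index("neuron_id")["type_name"]
        pre_exc = conn["pre_id"].map(type_of).isin(exc)
        assert set(conn.loc[pre_exc, "kind"]) <= {"AMPA", "NMDA"}
        assert set(conn.loc[~pre_exc, "kind"]) <= {"GABA_A"}

    def test_no_self_connections_and_valid_weights_delays(self):
        cfg = desk_scale_config(seed=6)
        pos = place_neurons(cfg)
        conn = build_connections(cfg, pos)
        assert (conn["pre_id"] != conn["post_id"]).all()
        assert (conn["weight"] > 0).all() and (conn["weight"] <= 1).all()
        assert (conn["delay_ms"] >= 0).all()
        # delays bounded by the patch diagonal (cortex + thalamic block)
        diag = np.sqrt(cfg.patch_xy_um ** 2 * 2 + 3400.0 ** 2)
        assert (conn["delay_ms"] <= diag * 1e-3).all()

    def test_realized_counts_match_binomial_expectation(self):
        # pool one high-p type pair over 20 seeds; expect the realized
        # count within 4 binomial standard deviations
        reg = default_cell_registry()
        pre_t, post_t = "L23_RS_pyramid", "L23_basket"
        p = 0.20                     # excitatory → inhibitory default
        total, n_pairs = 0, 0
        for seed in range(20):
            cfg = desk_scale_config(seed=seed)
            pos = place_neurons(cfg)
            conn = build_connections(cfg, pos)
            type_of = pos.set_index("neuron_id")["type_name"]
            rows = conn[(conn["pre_id"].map(type_of) == pre_t)
                        & (conn["post_id"].map(type_of) == post_t)
                        & (conn["kind"] == "AMPA")]
            total += len(rows)
            n_pre = (pos["type_name"] == pre_t).sum()
            n_post = (pos["type_name"] == post_t).sum()
            n_pairs += n_pre * n_post
        expected = n_pairs * p
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(total - expected) <= 4 * sd


class TestDrive:
    def test_driven_count_is_ten_percent(self):
        cfg = desk_scale_config(seed=9)
        drv = build_drive(cfg)
        assert len(drv.driven_ids) == round(0.10 * cfg.n_neurons)

    def test_zero_rate_gives_no_events(self):
        cfg = desk_scale_config(seed=9, drive_rate_per_step=0.0)
        drv = build_drive(cfg)
        assert drv.n_events == 0

    def test_event_count_within_binomial_bounds(self):
        # one driven neuron, lambda=0.005 per step over 20 s of 50 µs steps
        cfg = desk_scale_config(seed=13, duration_s=20.0)
        drv = build_drive(cfg)
        n_steps = cfg.n_steps
        mean = 0.005 * n_steps
        sd = np.sqrt(n_steps * 0.005 * 0.995)
        for ev in drv.event_steps:
            assert abs(len(ev) - mean) <= 4 * sd
            assert (np.diff(ev) > 0).all()
            assert ev.min() >= 0 and ev.max() < n_steps

    def test_same_seed_reproduces_drive(self):
        cfg = desk_scale_config(seed=21)
        d1, d2 = build_drive(cfg), build_drive(cfg)
        np.testing.assert_array_equal(d1.driven_ids, d2.driven_ids)
        for a, b in zip(d1.event_steps, d2.event_steps):
            np.testing.assert_array_equal(a, b)


def test_shipped_template_data_matches_builders():
    # the JSON package data is the serialised form of the programmatic
    # registry; they must not drift apart
    from cortexdamage.templates import load_templates
    built = {k: v.to_dict() for k, v in build_templates().items()}
    shipped = {k: v.to_dict() for k, v in load_templates().items()}
    assert built == shipped


def test_build_network_is_deterministic():
    cfg = desk_scale_config(seed=31)
    n1, n2 = build_network(cfg), build_network(cfg)
    pd.testing.assert_frame_equal(n1.positions, n2.positions)
    pd.testing.assert_frame_equal(n1.connections, n2.connections)
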