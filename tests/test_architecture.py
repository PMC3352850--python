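"""Network construction: Table fidelity, wiring, hardware report, severing."""
import numpy as np
import pytest

from burstnet.architecture import (
    DEFAULT_CONNECTIONS,
    DEFAULT_GROUPS,
    build_network,
    sever_attention,
    total_neurons,
    validate_hardware,
    wire_random,
    wire_topographic,
)
from burstnet.lif import INHIBITORY


# The published operating point, row for row: (name, type, rows, cols,
# train_only, T, L, S+, S-).  The retina is an input surface without
# neuron constants.
GOLDEN_ROWS = [
    ("Retina", "Ex", 10, 10, False, None, None, None, None),
    ("S1-ver", "Ex", 10, 5, False, 31, 16, 16, 0),
    ("S1-hor", "Ex", 5, 10, False, 31, 16, 16, 0),
    ("C1-ver-ex", "Ex", 10, 5, False, 4, 2, 8, 64),
    ("C1-hor-ex", "Ex", 5, 10, False, 4, 2, 8, 64),
    ("C1-ver-inh", "Inh", 10, 5, False, 4, 2, 32, 0),
    ("C1-hor-inh", "Inh", 5, 10, False, 4, 2, 32, 0),
    ("C1-ver-max", "Ex", 5, 5, False, 1, 2, 32, 0),
    ("C1-hor-max", "Ex", 5, 5, False, 16, 2, 32, 0),
    ("S2-shape-ex", "Ex", 6, 6, False, 100, 64, 32, 255),
    ("S2-shape-inh", "Inh", 6, 6, True, 2, 32, 32, 0),
    ("CLA-shape", "Ex", 3, 10, False, 16, 2, 32, 128),
    ("S1-inst", "Ex", 4, 4, False, 27, 26, 4, 0),
    ("S1-del", "Ex", 4, 4, False, 27, 26, 4, 0),
    ("S2-where-ex", "Ex", 4, 6, False, 100, 64, 64, 192),
    ("S2-where-inh", "Inh", 4, 6, True, 16, 2, 32, 0),
    ("CLA-where", "Ex", 8, 10, False, 32, 16, 64, 0),
    ("Attention", "Inh", 4, 6, False, 5, 16, 16, 128),
    ("Target", "Ex", 1, 8, False, 21, 5, 1, 80),
    ("Obstacle", "Ex", 1, 8, False, 21, 5, 1, 80),
    ("Shape-inh", "Inh", 1, 3, False, 4, 4, 1, 0),
    ("Shape-decision", "Ex", 1, 3, False, 13, 3, 1, 0),
    ("Motor", "Ex", 1, 8, False, 8, 7, 4, 0),
]


class TestGroupTable:
    def test_twenty_three_groups_under_a_thousand_neurons(self):
        assert len(DEFAULT_GROUPS) == 23
        assert total_neurons() < 1000
        assert total_neurons() == 766

    def test_retina_contributes_exactly_100(self):
        retina = next(g for g in DEFAULT_GROUPS if g.name == "Retina")
        assert retina.size == 100

    def test_golden_rows(self):
        by_name = {g.name: g for g in DEFAULT_GROUPS}
        assert list(by_name) == [r[0] for r in GOLDEN_ROWS]
        for name, typ, rows, cols, train_only, T, L, sp, sm in GOLDEN_ROWS:
            g = by_name[name]
            assert g.grid == (rows, cols), name
            assert (g.axon_type == INHIBITORY) == (typ == "Inh"), name
            assert g.train_only == train_only, name
            assert (g.threshold, g.leak, g.s_plus, g.s_minus) == (T, L, sp, sm), name

    def test_targets_resolve(self):
        names = {g.name for g in DEFAULT_GROUPS}
        for g in DEFAULT_GROUPS:
            assert set(g.targets) <= names

    def test_classifier_pool_layout(self):
        cla_where = next(g for g in DEFAULT_GROUPS if g.name == "CLA-where")
        assert cla_where.grid == (8, 10)  # 8 trajectory pools of 10 neurons
        cla_shape = next(g for g in DEFAULT_GROUPS if g.name == "CLA-shape")
        assert cla_shape.grid == (3, 10)  # one pool of 10 per letter


class TestWiring:
    def test_retina_tiling_for_presence_detectors(self):
        W = wire_topographic((10, 10), (4, 4), rf=(4, 4), stride=(2, 2))
        assert W.shape == (100, 16)
        assert (W.sum(axis=0) == 16).all()  # each destination reads 16 pixels

    def test_small_grid_window_enumeration(self):
        W = wire_topographic((6, 6), (3, 3), rf=(2, 2), stride=(2, 2))
        # brute-force window check: destination (i,j) reads exactly its block
        for i in range(3):
            for j in range(3):
                src = np.zeros((6, 6))
                src[2 * i: 2 * i + 2, 2 * j: 2 * j + 2] = 1
                got = src.ravel() @ W
                expect = np.zeros(9)
                expect[i * 3 + j] = 4
                assert np.array_equal(got, expect)

    def test_identity_receptive_field(self):
        W = wire_topographic((3, 4), (3, 4), rf=(1, 1), stride=(1, 1))
        assert np.array_equal(W, np.eye(12))

    def test_incompatible_tiling_rejected(self):
        with pytest.raises(ValueError):
            wire_topographic((10, 10), (5, 5), rf=(4, 4), stride=(2, 2))

    def test_random_weights_reproducible_and_in_range(self):
        a = wire_random(50, 36, np.random.default_rng(11))
        b = wire_random(50, 36, np.random.default_rng(11))
        assert np.array_equal(a, b)
        assert (a >= 0).all() and (a < 1).all()

    def test_random_weights_uniform_mean(self):
        w = wire_random(100, 100, np.random.default_rng(3))
        assert w.mean() == pytest.approx(0.5, abs=0.02)


class TestBuildNetwork:
    def test_build_instantiates_all_groups(self):
        net = build_network(rng_seed=0)
        assert len(net.sizes) == 23
        assert sum(net.sizes.values()) == 766

    def test_plastic_connections_random_fixed_connections_binaryish(self):
        net = build_network(rng_seed=0)
        for c in net.connections:
            if c.plastic:
                assert (c.weights >= 0).all() and (c.weights < 1).all()
                assert len(np.unique(c.weights)) > 10
            else:
                assert set(np.unique(c.weights)) <= {0.0, 1.0}

    def test_seed_determinism(self):
        n1, n2 = build_network(rng_seed=5), build_network(rng_seed=5)
        for c1, c2 in zip(n1.connections, n2.connections):
            assert np.array_equal(c1.weights, c2.weights)

    def test_attention_is_inhibitory_everywhere(self):
        net = build_network(rng_seed=0)
        assert net.params["Attention"].axon_type == INHIBITORY

    def test_delay_line_only_on_delayed_pathway(self):
        net = build_network(rng_seed=0)
        for c in net.connections:
            if c.target == "S1-del" and c.source == "Retina":
                assert c.delay > 1
            else:
                assert c.delay == 1


class TestHardwareReport:
    def test_defaults_pass_ranges_fail_binarity_before_consolidation(self):
        net = build_network(rng_seed=0)
        rep = validate_hardware(net)
        fails = {c.check for c in rep.failures()}
        assert fails == {"synapse_binarity"}

    def test_out_of_range_threshold_detected(self):
        from burstnet.lif import NeuronGroupParams

        with pytest.raises(ValueError):
            NeuronGroupParams(threshold=300, leak=0, s_plus=1, s_minus=0)

    def test_binarized_network_passes(self):
        from burstnet.plasticity import binarize_weights

        net = build_network(rng_seed=0)
        for c in net.connections:
            if c.plastic:
                c.weights = binarize_weights(c.weights, 0.5)
        assert validate_hardware(net).passed


class TestSeverAttention:
    def test_attention_outputs_zeroed_only(self):
        net = build_network(rng_seed=0)
        sever_attention(net)
        for c in net.connections:
            if c.source == "Attention":
                assert not c.weights.any()
            else:
                assert c.weights.any()

    def test_idempotent(self):
        net = build_network(rng_seed=0)
        sever_attention(net)
        snap = [c.weights.copy() for c in net.connections]
        sever_attention(net)
        for w, c in zip(snap, net.connections):
            assert np.array_equal(w, c.weights)

    def test_attention_spikes_have_no_downstream_effect(self):
        net = build_network(rng_seed=0)
        sever_attention(net)
        outgoing = [c for c in net.connections if c.source == "Attention"]
        spikes = np.ones(net.sizes["Attention"], dtype=bool)
        for c in outgoing:
            assert (spikes.astype(float) @ c.weights == 0).all()
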