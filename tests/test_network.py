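"""Net input, activation, settling and trial-level behaviour."""

import numpy as np
import pytest

from nmph.experiments import STIM_A, STIM_B, _stimulus_patterns, build_chanales
from nmph.network import Network, activation_function
from nmph.params import LayerParams, ProjectionParams, UShapeParams

_U = UShapeParams(0.2, 0.3, -1.0, 0.5, 0.5)


def two_layer_net(scale_fwd=2.0, scale_bwd=1.0, wt=0.99, batch=1):
    layers = {
        "a": LayerParams("a", 1, k=1, k_max=2, threshold=0.0, clamp_gain=1.0),
        "b": LayerParams("b", 3, k=1, threshold=0.0),
    }
    # k=1 sender with a 1-unit layer: divisor is 1, so net input is
    # wt_scale * w * activity exactly.
    projs = [ProjectionParams("a", "b", (wt, wt), scale_fwd, scale_bwd, _U)]
    return Network(layers, projs, batch=batch, seed=0)


class TestNetInput:
    def test_zero_activity_gives_zero_net_input(self):
        net = two_layer_net()
        assert np.all(net.compute_net_input("b") == 0.0)

    def test_single_sender_hand_value(self):
        net = two_layer_net(scale_fwd=2.0, wt=0.99)
        net.layers["a"].act[:] = 1.0
        assert np.allclose(net.compute_net_input("b"), 2.0 * 0.99)

    def test_linear_in_wt_scale(self):
        n1 = two_layer_net(scale_fwd=1.5)
        n2 = two_layer_net(scale_fwd=3.0)
        for n in (n1, n2):
            n.layers["a"].act[:] = 0.7
        assert np.allclose(2 * n1.compute_net_input("b"),
                           n2.compute_net_input("b"))

    def test_linear_in_sender_activity(self):
        net = two_layer_net()
        net.layers["a"].act[:] = 0.25
        low = net.compute_net_input("b").copy()
        net.layers["a"].act[:] = 0.5
        assert np.allclose(net.compute_net_input("b"), 2 * low)

    def test_clamp_term_added(self):
        net = two_layer_net()
        net.layers["a"].external = np.ones((1, 1))
        assert np.allclose(net.compute_net_input("a"), 1.0)  # clamp_gain 1

    def test_backward_direction_uses_bwd_scale(self):
        net = two_layer_net(scale_fwd=2.0, scale_bwd=0.5)
        net.layers["b"].act[:, 0] = 1.0
        # layer b has k=1 so divisor 1; one active sender with w=0.99
        assert np.allclose(net.compute_net_input("a"), 0.5 * 0.99)

    def test_projection_onto_missing_layer_rejected(self):
        layers = {"a": LayerParams("a", 2, k=1)}
        projs = [ProjectionParams("a", "zzz", (0.1, 0.2), 1.0, 1.0, _U)]
        with pytest.raises(ValueError, match="zzz"):
            Network(layers, projs, batch=1, seed=0)


class TestActivation:
    def test_zero_at_or_below_threshold(self):
        assert activation_function(0.2, 0.0, gain=100, threshold=0.25) == 0.0
        assert activation_function(0.25, 0.0, gain=100, threshold=0.25) == 0.0

    def test_half_activation_point(self):
        # gain 100 with drive 0.01 above threshold: 1/(1+1) = 0.5
        assert activation_function(0.26, 0.0, 100, 0.25) == pytest.approx(0.5)

    def test_bounded_below_one(self):
        assert activation_function(1e9, 0.0, 100, 0.0) < 1.0

    def test_monotone_in_drive_and_gain(self):
        drives = np.linspace(0, 2, 50)
        a = activation_function(drives, 0.5, 100, 0.1)
        assert np.all(np.diff(a) >= 0)
        assert activation_function(1.0, 0.0, 200, 0.0) > \
            activation_function(1.0, 0.0, 50, 0.0)

    def test_inhibition_shifts_drive(self):
        assert activation_function(1.0, 0.4, 100, 0.1) == \
            activation_function(0.6, 0.0, 100, 0.1)


class TestSettling:
    def test_dead_network_stays_silent(self, tiny_chanales):
        net, _ = tiny_chanales
        for proj in net.projections:
            proj.weights[:] = 0.0
        net.reset_trial()
        for _ in range(50):
            net.settle_cycle()
        for layer in net.layers.values():
            assert np.all(layer.act == 0.0)

    def test_clamped_unit_leads_unclamped(self, tiny_chanales):
        net, _ = tiny_chanales
        net.reset_trial()
        net.set_stimulus(_stimulus_patterns(net, np.array([STIM_A])))
        net.settle_cycle()
        cat = net.layers["category"].act[0]
        assert cat[1] > cat[0] and cat[1] > cat[2]

    def test_activities_bounded_every_cycle(self, tiny_chanales):
        net, _ = tiny_chanales
        net.reset_trial()
        net.set_stimulus(_stimulus_patterns(net, np.array([STIM_B])))
        for _ in range(200):
            net.settle_cycle(train=True)
            for layer in net.layers.values():
                assert np.all((layer.act >= 0.0) & (layer.act <= 1.0))

    def test_settles_before_oscillation_onset(self, tiny_chanales):
        net, _ = tiny_chanales
        net.reset_trial()
        net.set_stimulus(_stimulus_patterns(net, np.array([STIM_A])))
        prev = None
        for cycle in range(124):
            net.settle_cycle()
            if cycle == 122:
                prev = {n: l.act.copy() for n, l in net.layers.items()}
        change = max(np.abs(l.act - prev[n]).max()
                     for n, l in net.layers.items())
        assert change < 1e-4

    def test_prefix_independent_of_training_mode(self, tiny_chanales):
        # Oscillations only start at cycle 125, so the settled state at cycle
        # 124 is identical whether or not the trial will continue as training.
        net, _ = tiny_chanales
        states = []
        for train in (False, True):
            net.reset_trial()
            net.set_stimulus(_stimulus_patterns(net, np.array([STIM_A])))
            for _ in range(124):
                net.settle_cycle(train=train)
            states.append(net.layers["hidden"].act.copy())
        assert np.array_equal(states[0], states[1])


class TestTrials:
    def test_test_mode_is_side_effect_free(self, tiny_chanales):
        net, _ = tiny_chanales
        before = [p.weights.copy() for p in net.projections]
        stim = _stimulus_patterns(net, np.array([STIM_A]))
        snap1 = net.run_trial(stim, train=False)
        snap2 = net.run_trial(stim, train=False)
        for b, p in zip(before, net.projections):
            assert np.array_equal(b, p.weights)
        for name in snap1:
            assert np.array_equal(snap1[name], snap2[name])

    def test_train_mode_changes_weights(self, tiny_chanales):
        net, _ = tiny_chanales
        before = [p.weights.copy() for p in net.projections]
        net.run_trial(_stimulus_patterns(net, np.array([STIM_A])), train=True)
        changed = any(not np.array_equal(b, p.weights)
                      for b, p in zip(before, net.projections))
        assert changed

    def test_fixed_projection_never_learns(self, tiny_chanales):
        net, _ = tiny_chanales
        oo = net.projection("output", "output")
        before = oo.weights.copy()
        for stim in (STIM_A, STIM_B, STIM_A):
            net.run_trial(_stimulus_patterns(net, np.array([stim])), train=True)
        assert np.array_equal(before, oo.weights)

    def test_weights_stay_in_unit_interval_through_training(self, tiny_chanales):
        net, _ = tiny_chanales
        for stim in (STIM_A, STIM_B) * 3:
            net.run_trial(_stimulus_patterns(net, np.array([stim])), train=True)
            for proj in net.projections:
                assert np.all((proj.weights >= 0.0) & (proj.weights <= 1.0))

    def test_invalid_stimulus_rejected(self, tiny_chanales):
        net, _ = tiny_chanales
        stim = _stimulus_patterns(net, np.array([STIM_A]))
        stim["item"][:, :] = 1.0  # two active units
        with pytest.raises(ValueError, match="exactly one"):
            net.run_trial(stim, train=False)

    def test_same_seed_same_weights(self):
        n1, _ = build_chanales(overlap=3, seed=42, n_runs=2)
        n2, _ = build_chanales(overlap=3, seed=42, n_runs=2)
        for p1, p2 in zip(n1.projections, n2.projections):
            assert np.array_equal(p1.weights, p2.weights)
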