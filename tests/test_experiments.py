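"""Prewiring builders, trial schedules and sweeps."""

import dataclasses

import numpy as np
import pytest

from nmph.analysis import correlation_series
from nmph.experiments import (
    ExperimentConfig,
    build_chanales,
    build_favila,
    build_schlichting,
    lrate_sweep,
    osc_sweep,
    run_experiment,
)
from nmph.params import PREWIRE_STRENGTH


class TestChanalesBuilder:
    @pytest.mark.parametrize("overlap", range(6))
    def test_block_overlap_counts(self, overlap):
        _, layout = build_chanales(overlap, seed=0)
        assert len(layout.hidden_shared) == overlap
        assert len(layout.hidden_union) == 12 - overlap

    def test_zero_overlap_blocks_are_adjacent(self):
        _, layout = build_chanales(0, seed=0)
        assert layout.hidden_b.min() == layout.hidden_a.max() + 1

    def test_item_and_category_prewiring(self):
        net, layout = build_chanales(2, seed=0)
        ih = net.projection("item", "hidden").weights[0]
        assert np.all(ih[0, layout.hidden_a] == PREWIRE_STRENGTH)
        assert np.all(ih[1, layout.hidden_b] == PREWIRE_STRENGTH)
        ch = net.projection("category", "hidden").weights[0]
        assert np.all(ch[1, layout.hidden_union] == PREWIRE_STRENGTH)

    def test_topographic_output_recurrence(self):
        net, _ = build_chanales(1, seed=0)
        oo = net.projection("output", "output")
        assert not oo.spec.learnable
        w = oo.weights[0]
        n = w.shape[0]
        # interior rows have exactly 14 maximally strong neighbours (+/-7)
        for i in (10, 25, 40):
            assert np.sum(w[i] == PREWIRE_STRENGTH) == 14
        assert np.all(np.diag(w) == 0.0)

    def test_one_to_one_wiring_only_outside_pairmate_blocks(self):
        net, layout = build_chanales(2, seed=0)
        ho = net.projection("hidden", "output").weights[0]
        solo = np.setdiff1d(np.arange(50), layout.hidden_union)
        assert np.all(ho[solo, solo] == PREWIRE_STRENGTH)
        # pairmate blocks are wired block-to-block instead
        a = layout.hidden_a
        assert np.all(ho[np.ix_(a, layout.output_a)] == PREWIRE_STRENGTH)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            build_chanales(6, seed=0)


class TestFavilaBuilder:
    def test_same_face_converges_on_one_output_unit(self):
        net, layout = build_favila("same-face", seed=0)
        ho = net.projection("hidden", "output").weights[0]
        strong_in = np.sum(ho >= PREWIRE_STRENGTH, axis=0)
        assert np.sum(strong_in >= 10) == 1  # 6+6 senders minus 2 shared

    def test_different_face_uses_two_output_units(self):
        net, layout = build_favila("different-face", seed=0)
        ho = net.projection("hidden", "output").weights[0]
        strong_in = np.sum(ho >= PREWIRE_STRENGTH, axis=0)
        assert np.sum(strong_in == 6) == 2
        assert layout.output_a[0] != layout.output_b[0]

    @pytest.mark.parametrize("condition", ["same-face", "different-face"])
    def test_hidden_overlap_is_two(self, condition):
        _, layout = build_favila(condition, seed=0)
        assert len(layout.hidden_shared) == 2

    def test_no_output_recurrence(self):
        net, _ = build_favila("same-face", seed=0)
        senders = {(p.spec.sender, p.spec.receiver) for p in net.projections}
        assert ("output", "output") not in senders


class TestSchlichtingBuilder:
    def test_blocked_prewire_strengths(self):
        net, layout = build_schlichting("blocked", seed=0)
        ho = net.projection("hidden", "output").weights[0]
        x = layout.output_a[0]
        uniq_b = np.setdiff1d(layout.hidden_b, layout.hidden_a)
        assert np.allclose(ho[np.setdiff1d(layout.hidden_a, uniq_b), x], 0.999)
        assert np.allclose(ho[uniq_b, x], 0.7)

    def test_interleaved_prewire_strengths(self):
        net, layout = build_schlichting("interleaved", seed=0)
        ho = net.projection("hidden", "output").weights[0]
        x = layout.output_a[0]
        uniq_b = np.setdiff1d(layout.hidden_b, layout.hidden_a)
        assert np.allclose(ho[layout.hidden_a, x], 0.8)
        assert np.allclose(ho[uniq_b, x], 0.7)

    @pytest.mark.parametrize("osc", [0.0623, 0.0525, 0.09])
    def test_oscillation_variant_installed(self, osc):
        net, _ = build_schlichting("interleaved", osc_variant=osc, seed=0)
        assert net.layers["hidden"].spec.osc == osc

    def test_shared_output_unit(self):
        _, layout = build_schlichting("blocked", seed=0)
        assert layout.output_a[0] == layout.output_b[0]


class TestSchedules:
    def test_snapshot_counts(self):
        cfg = ExperimentConfig("chanales", 2, n_runs=3, n_epochs=4, seed=9)
        res = run_experiment(cfg)
        assert res.hidden.shape == (5, 2, 3, 50)   # baseline + 4 epochs
        assert res.output.shape == (5, 2, 3, 50)

    def test_each_pairmate_once_per_epoch(self):
        cfg = ExperimentConfig("favila", "same-face", n_runs=4, n_epochs=3, seed=9)
        res = run_experiment(cfg)
        assert np.all(np.sort(res.train_orders, axis=2) == [0, 1])

    def test_blocked_has_no_pairmate_a_trials(self):
        cfg = ExperimentConfig("schlichting", "blocked", n_runs=2, n_epochs=3, seed=9)
        res = run_experiment(cfg)
        assert np.all(res.train_orders == 1)
        assert np.all(res.pairmate1 == 1)

    def test_interleaved_shows_b_first_every_epoch(self):
        cfg = ExperimentConfig("schlichting", "interleaved", n_runs=2,
                               n_epochs=3, seed=9)
        res = run_experiment(cfg)
        assert np.all(res.train_orders[:, :, 0] == 1)
        assert np.all(res.train_orders[:, :, 1] == 0)

    def test_reproducible_from_seed(self):
        cfg = ExperimentConfig("chanales", 2, n_runs=2, n_epochs=2, seed=77)
        r1 = run_experiment(cfg)
        r2 = run_experiment(cfg)
        assert np.array_equal(r1.hidden, r2.hidden)
        assert np.array_equal(r1.output, r2.output)
        assert np.array_equal(r1.train_orders, r2.train_orders)

    def test_invalid_conditions_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig("chanales", 7)
        with pytest.raises(ValueError):
            ExperimentConfig("favila", "blocked")
        with pytest.raises(ValueError):
            ExperimentConfig("nonesuch", 1)

    def test_baseline_correlation_increases_with_overlap(self):
        base = []
        for o in range(6):
            cfg = ExperimentConfig("chanales", o, n_runs=2, n_epochs=1, seed=5)
            res = run_experiment(cfg)
            base.append(np.nanmean(correlation_series(res)[0]))
        assert np.all(np.diff(base) > 0)


class TestSweeps:
    def test_zero_lrate_freezes_correlations(self):
        cfg = ExperimentConfig("chanales", 3, n_runs=2, n_epochs=3, seed=4)
        res = lrate_sweep(cfg, (0.0,))[0.0]
        series = correlation_series(res)
        assert np.allclose(series, series[0], atol=1e-12)

    def test_sweep_sizes_and_keys(self):
        cfg = ExperimentConfig("chanales", 2, n_runs=2, n_epochs=1, seed=4)
        out = lrate_sweep(cfg, (0.25, 1.0))
        assert set(out) == {0.25, 1.0}

    def test_osc_sweep_only_changes_hidden_oscillation(self):
        cfg = ExperimentConfig("schlichting", "blocked", n_runs=1, n_epochs=1, seed=4)
        out = osc_sweep(cfg, (0.0525, 0.09))
        c1 = out[0.0525].config
        c2 = out[0.09].config
        assert dataclasses.replace(c1, osc=None) == dataclasses.replace(c2, osc=None)

    def test_empty_sweeps_rejected(self):
        cfg = ExperimentConfig("chanales", 2, n_runs=1, n_epochs=1, seed=4)
        with pytest.raises(ValueError):
            lrate_sweep(cfg, ())
        with pytest.raises(ValueError):
            lrate_sweep(cfg, (-0.5,))
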