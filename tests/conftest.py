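"""Shared fixtures.

The full-scale simulations (50 runs x 20 epochs per condition) are expensive,
so they are computed once per session and shared by every test that needs
them.  Small throwaway networks are built per-test.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmph.experiments import (
    ExperimentConfig,
    build_chanales,
    lrate_sweep,
    run_experiment,
)

MASTER_SEED = 1
N_RUNS = 50
N_EPOCHS = 20


def _config(study, condition, **kw):
    kw.setdefault("n_runs", N_RUNS)
    kw.setdefault("n_epochs", N_EPOCHS)
    kw.setdefault("seed", MASTER_SEED)
    return ExperimentConfig(study, condition, **kw)


@pytest.fixture(scope="session")
def chanales_curve():
    """Full overlap curve of the color-similarity study (0/6..5/6)."""
    return {o: run_experiment(_config("chanales", o)) for o in range(6)}


@pytest.fixture(scope="session")
def chanales_lrate_low():
    """Overlap conditions 2..5 re-run at learning rate 0.1."""
    return {o: run_experiment(_config("chanales", o, lrate=0.1))
            for o in (2, 3, 4, 5)}


@pytest.fixture(scope="session")
def chanales_2of6_lrate_half():
    return run_experiment(_config("chanales", 2, lrate=0.5))


@pytest.fixture(scope="session")
def favila_results():
    return {cond: run_experiment(_config("favila", cond))
            for cond in ("same-face", "different-face")}


@pytest.fixture(scope="session")
def schlichting_results():
    """Both curricula at the three hidden oscillation amplitudes."""
    return {
        (cond, osc): run_experiment(_config("schlichting", cond, osc=osc))
        for osc in (0.0623, 0.0525, 0.09)
        for cond in ("blocked", "interleaved")
    }


@pytest.fixture()
def tiny_chanales():
    """A single-run color-similarity network at 2/6 overlap."""
    net, layout = build_chanales(overlap=2, seed=123, n_runs=1)
    return net, layout


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
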