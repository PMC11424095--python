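"""Prewiring builders and trial schedules for the three simulated studies.

Each builder installs the study's parameter tables, draws the random
background weights from per-run seeded generators, and overwrites the
pre-wired entries that define the initial pairmate memories:

* ``build_chanales``: two 6-unit hidden blocks sharing ``overlap`` units,
  mirrored in a topographic 50-unit color output layer with fixed +/-7
  neighbour recurrence; overlap (0-5 of 6) manipulates stimulus similarity.
* ``build_favila``: 2/6 hidden overlap; both pairmates strongly wired to one
  shared output (face) unit, or to two different ones.
* ``build_schlichting``: same-associate structure, with the A->X strength
  encoding how much A-X training preceded the first B-X trial (0.999 blocked,
  0.8 interleaved; B->X is 0.7 in both).

``run_experiment`` runs the full schedule — a baseline test epoch, then
``n_epochs`` x (training epoch + test epoch) — for a batch of independent
runs and returns the per-epoch activity snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import params as P
from .network import Network
from .params import PREWIRE_STRENGTH, study_layers, study_projections

#: Hidden-layer oscillation amplitudes tested for the curriculum study
#: (intermediate, low, high).  A Methods-text variant 0.0535 of the low value
#: is accepted anywhere an amplitude is configurable.
SCHLICHTING_OSC_VARIANTS = (0.0623, 0.0525, 0.09)

#: Default learning-rate sweep.
DEFAULT_LRATES = (0.1, 0.25, 0.5, 1.0)

# Start of the pairmate-A hidden/output block (blocks sit centrally so the
# +/-7 topographic recurrence never reaches a layer boundary, even after the
# competitor representation shifts away).
_BLOCK_START = 22
_BLOCK_SIZE = 6
_TOPO_NEIGHBORS = 7

STIM_A, STIM_B = 0, 1
STIM_NAMES = ("A", "B")


@dataclass(frozen=True)
class StudyLayout:
    """Unit-index bookkeeping for a built network."""

    hidden_a: np.ndarray
    hidden_b: np.ndarray
    output_a: np.ndarray
    output_b: np.ndarray

    @property
    def hidden_shared(self) -> np.ndarray:
        return np.intersect1d(self.hidden_a, self.hidden_b)

    @property
    def hidden_union(self) -> np.ndarray:
        return np.union1d(self.hidden_a, self.hidden_b)


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings for one condition of one study."""

    study: str
    condition: str | int
    osc: float | None = None       # hidden-layer oscillation override
    lrate: float | None = None     # learning-rate override (learnable projections)
    n_runs: int = 50
    n_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study == "chanales":
            if self.condition not in range(6):
                raise ValueError("chanales condition is the hidden overlap, 0..5")
        elif self.study == "favila":
            if self.condition not in ("same-face", "different-face"):
                raise ValueError(
                    "favila condition must be 'same-face' or 'different-face'")
        elif self.study == "schlichting":
            if self.condition not in ("blocked", "interleaved"):
                raise ValueError(
                    "schlichting condition must be 'blocked' or 'interleaved'")
        else:
            raise ValueError(f"unknown study: {self.study!r}")
        if self.n_runs < 1 or self.n_epochs < 1:
            raise ValueError("n_runs and n_epochs must be >= 1")


def _hidden_blocks(overlap: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.arange(_BLOCK_START, _BLOCK_START + _BLOCK_SIZE)
    b_start = _BLOCK_START + _BLOCK_SIZE - overlap
    b = np.arange(b_start, b_start + _BLOCK_SIZE)
    return a, b


def build_chanales(overlap: int, seed=None, n_runs: int = 1,
                   lrate: float | None = None,
                   hidden_osc: float | None = None) -> tuple[Network, StudyLayout]:
    """Color-similarity network: ``overlap`` of 6 hidden/output units shared."""
    if overlap not in range(6):
        raise ValueError(f"overlap must be in 0..5, got {overlap}")
    net = Network(study_layers("chanales", hidden_osc=hidden_osc),
                  study_projections("chanales", lrate=lrate),
                  batch=n_runs, seed=seed)
    hid_a, hid_b = _hidden_blocks(overlap)
    layout = StudyLayout(hid_a, hid_b, hid_a.copy(), hid_b.copy())
    union = layout.hidden_union

    net.projection("item", "hidden").prewire([STIM_A], hid_a)
    net.projection("item", "hidden").prewire([STIM_B], hid_b)
    net.projection("category", "hidden").prewire([1], union)
    hh = net.projection("hidden", "hidden")
    hh.prewire(hid_a, hid_a)
    hh.prewire(hid_b, hid_b)

    ho = net.projection("hidden", "output")
    ho.prewire(hid_a, layout.output_a)
    ho.prewire(hid_b, layout.output_b)
    # Non-pairmate hidden units keep the color topography: one-to-one with the
    # output unit directly above.
    n_hidden = net.layers["hidden"].spec.n_units
    solo = np.setdiff1d(np.arange(n_hidden), union)
    ho.weights[:, solo, solo] = PREWIRE_STRENGTH

    # Fixed topographic color recurrence: +/-7 neighbours, maximally strong.
    oo = net.projection("output", "output")
    n_out = net.layers["output"].spec.n_units
    idx = np.arange(n_out)
    ring = (np.abs(idx[:, None] - idx[None, :]) <= _TOPO_NEIGHBORS) & \
           (idx[:, None] != idx[None, :])
    oo.weights[:, ring] = PREWIRE_STRENGTH
    return net, layout


def build_favila(condition: str, seed=None, n_runs: int = 1,
                 lrate: float | None = None,
                 hidden_osc: float | None = None) -> tuple[Network, StudyLayout]:
    """Shared- vs different-associate network (2/6 hidden overlap)."""
    if condition not in ("same-face", "different-face"):
        raise ValueError(f"invalid condition: {condition!r}")
    net = Network(study_layers("favila", hidden_osc=hidden_osc),
                  study_projections("favila", lrate=lrate),
                  batch=n_runs, seed=seed)
    hid_a, hid_b = _hidden_blocks(overlap=2)
    face_a = 4
    face_b = 4 if condition == "same-face" else 5
    layout = StudyLayout(hid_a, hid_b, np.array([face_a]), np.array([face_b]))

    net.projection("item", "hidden").prewire([STIM_A], hid_a)
    net.projection("item", "hidden").prewire([STIM_B], hid_b)
    net.projection("category", "hidden").prewire([1], layout.hidden_union)
    hh = net.projection("hidden", "hidden")
    hh.prewire(hid_a, hid_a)
    hh.prewire(hid_b, hid_b)
    ho = net.projection("hidden", "output")
    ho.prewire(hid_a, [face_a])
    ho.prewire(hid_b, [face_b])
    return net, layout


def build_schlichting(condition: str, osc_variant: float = 0.0623, seed=None,
                      n_runs: int = 1,
                      lrate: float | None = None) -> tuple[Network, StudyLayout]:
    """Blocked/interleaved curriculum network (single shared X associate)."""
    if condition not in ("blocked", "interleaved"):
        raise ValueError(f"invalid condition: {condition!r}")
    net = Network(study_layers("schlichting", hidden_osc=osc_variant),
                  study_projections("schlichting", lrate=lrate),
                  batch=n_runs, seed=seed)
    hid_a, hid_b = _hidden_blocks(overlap=2)
    x_unit = 4
    layout = StudyLayout(hid_a, hid_b, np.array([x_unit]), np.array([x_unit]))

    net.projection("item", "hidden").prewire([STIM_A], hid_a)
    net.projection("item", "hidden").prewire([STIM_B], hid_b)
    net.projection("category", "hidden").prewire([1], layout.hidden_union)
    hh = net.projection("hidden", "hidden")
    hh.prewire(hid_a, hid_a)
    hh.prewire(hid_b, hid_b)
    ho = net.projection("hidden", "output")
    # B->X reflects partial B-X knowledge; A->X reflects how much A-X training
    # preceded the first B-X trial.  Shared units carry the (stronger) A value.
    ho.prewire(hid_b, [x_unit], strength=0.7)
    a_strength = 0.999 if condition == "blocked" else 0.8
    ho.prewire(hid_a, [x_unit], strength=a_strength)
    return net, layout


def build_network(config: ExperimentConfig) -> tuple[Network, StudyLayout]:
    """Dispatch to the study builder for a resolved configuration."""
    seed = np.random.SeedSequence([config.seed, 0])
    if config.study == "chanales":
        return build_chanales(config.condition, seed=seed, n_runs=config.n_runs,
                              lrate=config.lrate, hidden_osc=config.osc)
    if config.study == "favila":
        return build_favila(config.condition, seed=seed, n_runs=config.n_runs,
                            lrate=config.lrate, hidden_osc=config.osc)
    osc = 0.0623 if config.osc is None else config.osc
    return build_schlichting(config.condition, osc_variant=osc, seed=seed,
                             n_runs=config.n_runs, lrate=config.lrate)


@dataclass
class ExperimentResult:
    """Per-run, per-test-epoch activity snapshots and schedule bookkeeping.

    ``hidden`` and ``output`` have shape (n_epochs+1, 2, n_runs, n_units):
    axis 0 is the test epoch (0 = baseline), axis 1 the test stimulus (A, B).
    ``pairmate1`` gives, per run, which stimulus (0=A, 1=B) was presented
    first on the first training epoch.
    """

    config: ExperimentConfig
    layout: StudyLayout
    hidden: np.ndarray
    output: np.ndarray
    pairmate1: np.ndarray
    train_orders: np.ndarray  # (n_epochs, n_runs, trials_per_epoch)

    @property
    def n_runs(self) -> int:
        return self.hidden.shape[2]

    @property
    def n_epochs(self) -> int:
        return self.hidden.shape[0] - 1

    def hidden_pattern(self, epoch: int, stimulus: int) -> np.ndarray:
        return self.hidden[epoch, stimulus]

    def output_pattern(self, epoch: int, stimulus: int) -> np.ndarray:
        return self.output[epoch, stimulus]


def _stimulus_patterns(net: Network, which: np.ndarray) -> dict[str, np.ndarray]:
    """Clamp patterns for a per-run stimulus assignment (0=A, 1=B)."""
    b = net.batch
    category = np.zeros((b, net.layers["category"].spec.n_units))
    category[:, 1] = 1.0  # middle category unit shared by the pairmates
    item = np.zeros((b, net.layers["item"].spec.n_units))
    item[np.arange(b), which] = 1.0
    return {"category": category, "item": item}


def _test_epoch(net: Network, hidden_out: np.ndarray, output_out: np.ndarray) -> None:
    """Run test trials for A and B (no oscillation, no learning)."""
    b = net.batch
    for stim in (STIM_A, STIM_B):
        snap = net.run_trial(_stimulus_patterns(net, np.full(b, stim)), train=False)
        hidden_out[stim] = snap["hidden"]
        output_out[stim] = snap["output"]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full train/test schedule for one condition.

    Every run sees a baseline test epoch, then ``n_epochs`` repetitions of a
    training epoch followed by a test epoch.  Training order is randomized
    per run and epoch, except for the curriculum study where B always comes
    first (and, when blocked, no A trials occur at all).  Fully reproducible
    from ``config.seed``.
    """
    net, layout = build_network(config)
    b, e = config.n_runs, config.n_epochs
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_hidden = net.layers["hidden"].spec.n_units
    n_output = net.layers["output"].spec.n_units
    hidden = np.zeros((e + 1, 2, b, n_hidden))
    output = np.zeros((e + 1, 2, b, n_output))

    if config.study == "schlichting":
        if config.condition == "blocked":
            base_order = np.array([STIM_B])
        else:
            base_order = np.array([STIM_B, STIM_A])
        orders = np.tile(base_order, (e, b, 1))
    else:
        orders = np.stack([
            order_rng.permuted(np.tile([STIM_A, STIM_B], (b, 1)), axis=1)
            for _ in range(e)
        ])

    _test_epoch(net, hidden[0], output[0])
    for epoch in range(e):
        for t in range(orders.shape[2]):
            net.run_trial(_stimulus_patterns(net, orders[epoch, :, t]), train=True)
        _test_epoch(net, hidden[epoch + 1], output[epoch + 1])

    return ExperimentResult(config=config, layout=layout, hidden=hidden,
                            output=output, pairmate1=orders[0, :, 0].copy(),
                            train_orders=orders)


def lrate_sweep(config: ExperimentConfig,
                lrates=DEFAULT_LRATES) -> dict[float, ExperimentResult]:
    """Re-run one condition at several learning rates (same seeds).

    The override applies to every learnable projection; the fixed topographic
    output recurrence keeps its zero learning rate.
    """
    if not lrates:
        raise ValueError("lrates must be non-empty")
    if any(lr < 0 for lr in lrates):
        raise ValueError("learning rates must be >= 0")
    return {lr: run_experiment(replace(config, lrate=lr)) for lr in lrates}


def osc_sweep(config: ExperimentConfig,
              variants=SCHLICHTING_OSC_VARIANTS) -> dict[float, ExperimentResult]:
    """Re-run one condition at several hidden-layer oscillation amplitudes."""
    if not variants:
        raise ValueError("variants must be non-empty")
    return {v: run_experiment(replace(config, osc=v)) for v in variants}
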