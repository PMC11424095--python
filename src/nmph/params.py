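"""Default parameters for the three simulated studies.

The model reuses one architecture — category/item input layers, a hidden
layer, and an output layer — across three simulated experiments:

* ``chanales``: stimulus-similarity manipulation with a topographic
  (color-wheel-like) output layer,
* ``favila``: shared vs. different associate (face) in the output layer,
* ``schlichting``: blocked vs. interleaved curriculum with a single shared
  associate.

Per-layer inhibitory/activity parameters, per-projection weight ranges and
scales, and per-projection U-shaped learning parameters are study-specific
and collected here.  ``INFINITY`` marks an unbounded winner cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

INFINITY = math.inf

#: Activation threshold: drive below this yields zero activity.  A unit fed
#: only by the shared category input sits below this floor, which is what
#: keeps severed representations from reigniting (see docs/methods.md).
DEFAULT_THRESHOLD = 0.25

#: Threshold of the weakly clamped item layer.  Its external drive and the
#: feedback it receives are small, so its floor sits proportionally lower;
#: this is what lets the competitor's item unit pop up when inhibition falls.
ITEM_THRESHOLD = 0.0

#: Exponent of the net-input normalization convention: each projection's
#: summed input is divided by k**lam * N**(1-lam) of the sending layer
#: (lam=1: expected active count, the convention used here; lam=0: sender
#: count).
NET_NORM_EXPONENT = 1.0

#: Step size of the exponential approach of activity to its instantaneous
#: target, per cycle.  Set so that a unit popping up late in the oscillation
#: trough rises over tens of cycles: the competitor's trial-averaged trace
#: then grades with how early the falling inhibition reaches it.
DEFAULT_DT = 0.104

#: Integration step of the small clamped input layers, which settle faster
#: than the large interior layers.
INPUT_DT = 0.2

#: Number of settling cycles per trial.
TRIAL_CYCLES = 200

#: First cycle (1-based) at which the inhibitory oscillation is applied
#: during training trials; one full sine period spans cycles 125-200.
OSC_ONSET = 125
OSC_PERIOD = TRIAL_CYCLES - OSC_ONSET

#: Net-input normalization count of the single-winner associate output layer
#: used in the shared-associate and curriculum studies.  The directional
#: calibration constant of the default configuration: it balances the shared
#: associate's feedback against the item and recurrent pathways.
ASSOCIATE_NORM_COUNT = 4.0

#: Strength of pre-wired, non-random connections unless stated otherwise.
PREWIRE_STRENGTH = 0.99


@dataclass(frozen=True)
class UShapeParams:
    """Five-parameter U-shaped learning function plus learning rate.

    ``d_thr``, ``d_rev`` and ``thr_p`` are coactivity abscissae; ``d_rev_mag``
    (<= 0) is the peak weakening at ``d_rev`` and ``d_max_mag`` (>= 0) the peak
    strengthening attained at coactivity 1.
    """

    d_thr: float
    d_rev: float
    d_rev_mag: float
    thr_p: float
    d_max_mag: float
    lrate: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_thr < self.d_rev < self.thr_p <= 1.0):
            raise ValueError(
                "U-shape abscissae must satisfy 0 <= d_thr < d_rev < thr_p <= 1, "
                f"got d_thr={self.d_thr}, d_rev={self.d_rev}, thr_p={self.thr_p}"
            )
        if self.d_rev_mag > 0 or self.d_max_mag < 0:
            raise ValueError("require d_rev_mag <= 0 <= d_max_mag")
        if self.lrate < 0:
            raise ValueError("lrate must be non-negative")


@dataclass(frozen=True)
class LayerParams:
    """Structural and inhibitory parameters of one layer."""

    name: str
    n_units: int
    k: int
    k_max: float = INFINITY  # float to allow INFINITY
    kwta_point: float = 0.75
    target_diff: float = 0.0
    osc: float = 0.0
    gain: float = 100.0
    clamp_gain: float = 0.0
    threshold: float = DEFAULT_THRESHOLD
    dt: float | None = None  # per-layer integration step; None = network default
    norm_count: float | None = None  # net-input divisor when this layer sends
                                     # (None: k**lam * N**(1-lam))

    def __post_init__(self) -> None:
        if self.n_units <= 0 or self.k <= 0:
            raise ValueError(f"layer {self.name}: n_units and k must be positive")
        k_max_eff = min(self.k_max, self.n_units)
        if self.k > k_max_eff:
            raise ValueError(
                f"layer {self.name}: require k <= k_max <= n_units "
                f"(k={self.k}, k_max={self.k_max}, n_units={self.n_units})"
            )
        if not 0.0 <= self.kwta_point <= 1.0:
            raise ValueError(f"layer {self.name}: kwta_point must be in [0, 1]")
        if self.target_diff < 0 or self.osc < 0 or self.gain <= 0:
            raise ValueError(f"layer {self.name}: invalid inhibition parameters")

    @property
    def k_max_effective(self) -> int:
        return int(min(self.k_max, self.n_units))


@dataclass(frozen=True)
class ProjectionParams:
    """Parameters of one bidirectional projection (single shared matrix)."""

    sender: str
    receiver: str
    wt_range: tuple[float, float]
    scale_fwd: float
    scale_bwd: float
    ushape: UShapeParams
    learnable: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.wt_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("wt_range must satisfy 0 <= low <= high <= 1")
        if self.scale_fwd <= 0 or self.scale_bwd <= 0:
            raise ValueError("wt_scale values must be positive")


# Layer sizes.  The input layers carry one-hot stimuli: the middle category
# unit is shared by the pairmates and the two item units distinguish them.
N_CATEGORY = 3
N_ITEM = 2
N_HIDDEN = 50
N_OUTPUT_TOPOGRAPHIC = 50  # chanales color layer (mirrors the hidden layer)
N_OUTPUT_ASSOCIATE = 10    # favila / schlichting associate layer

# A placeholder U-shape for non-learnable projections (never applied).
_FIXED = UShapeParams(0.5, 0.6, -0.1, 0.7, 0.1, lrate=0.0)


def _layers_chanales() -> dict[str, LayerParams]:
    return {
        "category": LayerParams("category", N_CATEGORY, k=1, kwta_point=0.75,
                                target_diff=0.0, osc=0.0, gain=100, clamp_gain=2.0,
                                dt=INPUT_DT),
        "item": LayerParams("item", N_ITEM, k=1, kwta_point=0.95,
                            target_diff=0.2, osc=0.22, gain=100, clamp_gain=0.3,
                            threshold=ITEM_THRESHOLD, dt=INPUT_DT),
        "hidden": LayerParams("hidden", N_HIDDEN, k=6, k_max=10, kwta_point=0.75,
                              target_diff=0.03, osc=0.11, gain=100),
        "output": LayerParams("output", N_OUTPUT_TOPOGRAPHIC, k=6, k_max=15,
                              kwta_point=0.95, target_diff=0.05, osc=0.115, gain=30),
    }


def _layers_favila() -> dict[str, LayerParams]:
    return {
        "category": LayerParams("category", N_CATEGORY, k=1, kwta_point=0.75,
                                target_diff=0.0, osc=0.0, gain=100, clamp_gain=2.0,
                                dt=INPUT_DT),
        "item": LayerParams("item", N_ITEM, k=1, kwta_point=0.95,
                            target_diff=0.2, osc=0.2, gain=100, clamp_gain=0.3,
                            threshold=ITEM_THRESHOLD, dt=INPUT_DT),
        "hidden": LayerParams("hidden", N_HIDDEN, k=6, k_max=10, kwta_point=0.8,
                              target_diff=0.02, osc=0.067, gain=100),
        "output": LayerParams("output", N_OUTPUT_ASSOCIATE, k=1, kwta_point=0.75,
                              target_diff=0.03, osc=0.07, gain=100,
                              norm_count=ASSOCIATE_NORM_COUNT),
    }


def _layers_schlichting(hidden_osc: float = 0.0623) -> dict[str, LayerParams]:
    return {
        "category": LayerParams("category", N_CATEGORY, k=1, kwta_point=0.75,
                                target_diff=0.0, osc=0.0, gain=100, clamp_gain=2.0,
                                dt=INPUT_DT),
        "item": LayerParams("item", N_ITEM, k=1, kwta_point=0.95,
                            target_diff=0.2, osc=0.156, gain=100, clamp_gain=0.3,
                            threshold=ITEM_THRESHOLD, dt=INPUT_DT),
        "hidden": LayerParams("hidden", N_HIDDEN, k=6, k_max=10, kwta_point=0.8,
                              target_diff=0.02, osc=hidden_osc, gain=100),
        "output": LayerParams("output", N_OUTPUT_ASSOCIATE, k=1, kwta_point=0.75,
                              target_diff=0.03, osc=0.03, gain=100,
                              norm_count=ASSOCIATE_NORM_COUNT),
    }


def _projections_chanales() -> list[ProjectionParams]:
    return [
        ProjectionParams("hidden", "hidden", (0.45, 0.55), 1.8, 1.8,
                         UShapeParams(0.15, 0.24, -4.5, 0.4, 0.1)),
        ProjectionParams("hidden", "output", (0.01, 0.03), 3.0, 2.0,
                         UShapeParams(0.1, 0.44, -10.0, 0.6, 1.5)),
        ProjectionParams("category", "hidden", (0.01, 0.03), 0.2, 0.2,
                         UShapeParams(0.2, 0.3, -0.1, 0.46, 0.06)),
        ProjectionParams("item", "hidden", (0.45, 0.55), 0.2, 0.2,
                         UShapeParams(0.2, 0.3, -2.5, 0.46, 0.3)),
        # Topographic color recurrence: fixed, never learned.
        ProjectionParams("output", "output", (0.01, 0.03), 1.0, 1.0,
                         UShapeParams(0.53, 0.6, -0.3, 0.68, 0.3, lrate=0.0),
                         learnable=False),
    ]


def _projections_favila() -> list[ProjectionParams]:
    return [
        ProjectionParams("hidden", "hidden", (0.45, 0.55), 1.8, 1.8,
                         UShapeParams(0.11, 0.23, -1.5, 0.4, 0.1)),
        ProjectionParams("hidden", "output", (0.01, 0.03), 1.2, 1.7,
                         UShapeParams(0.11, 0.23, -0.01, 0.4, 0.5)),
        ProjectionParams("category", "hidden", (0.01, 0.03), 0.1, 0.1,
                         UShapeParams(0.2, 0.3, -0.1, 0.46, 0.06)),
        ProjectionParams("item", "hidden", (0.45, 0.55), 0.3, 0.2,
                         UShapeParams(0.215, 0.4, -2.5, 0.6, 0.3)),
    ]


def _projections_schlichting() -> list[ProjectionParams]:
    return [
        ProjectionParams("hidden", "hidden", (0.45, 0.55), 1.9, 1.9,
                         UShapeParams(0.11, 0.23, -1.5, 0.4, 1.0)),
        ProjectionParams("hidden", "output", (0.01, 0.03), 1.2, 1.7,
                         UShapeParams(0.11, 0.23, -0.01, 0.4, 0.5)),
        ProjectionParams("category", "hidden", (0.01, 0.03), 0.2, 0.1,
                         UShapeParams(0.2, 0.3, -0.1, 0.46, 0.06)),
        ProjectionParams("item", "hidden", (0.45, 0.55), 0.3, 0.2,
                         UShapeParams(0.11, 0.23, -1.5, 0.4, 1.0)),
    ]


def study_layers(study: str, hidden_osc: float | None = None) -> dict[str, LayerParams]:
    """Default layer parameter table for one study.

    ``hidden_osc`` overrides the hidden-layer oscillation amplitude (the
    manipulation used to emulate regional inhibitory differences).
    """
    if study == "chanales":
        layers = _layers_chanales()
    elif study == "favila":
        layers = _layers_favila()
    elif study == "schlichting":
        layers = _layers_schlichting()
    else:
        raise ValueError(f"unknown study: {study!r}")
    if hidden_osc is not None:
        layers["hidden"] = replace(layers["hidden"], osc=hidden_osc)
    return layers


def study_projections(study: str, lrate: float | None = None) -> list[ProjectionParams]:
    """Default projection parameter table for one study.

    ``lrate`` overrides the learning rate on every *learnable* projection
    (the fixed topographic output recurrence keeps learning rate zero).
    """
    if study == "chanales":
        projs = _projections_chanales()
    elif study == "favila":
        projs = _projections_favila()
    elif study == "schlichting":
        projs = _projections_schlichting()
    else:
        raise ValueError(f"unknown study: {study!r}")
    if lrate is not None:
        projs = [
            replace(p, ushape=replace(p.ushape, lrate=lrate)) if p.learnable else p
            for p in projs
        ]
    return projs
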