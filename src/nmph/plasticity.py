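"""Running-average activity traces, coactivity, and the U-shaped learning rule.

Weight changes are computed once per training trial from the *coactivity* of
each connected unit pair — the product of the two units' medium-term running
average activities at the end of the trial.  The coactivity is mapped through
a five-parameter U-shaped function: zero below ``d_thr``, weakening (down to
``d_rev_mag`` at ``d_rev``, back to zero at ``thr_p``), then strengthening up
to ``d_max_mag`` at coactivity 1.  Low competitor activity therefore leaves
weights alone, moderate activity severs connections (differentiation), and
high activity strengthens them (integration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import UShapeParams


@dataclass(frozen=True)
class TraceParams:
    """Time-scale constants of the cascaded running averages."""

    alpha_super_short: float = 0.5
    alpha_short: float = 0.5
    alpha_raw_medium: float = 0.1
    alpha_mix: float = 0.9   # weight on the raw medium-term trace
    beta_mix: float = 0.1    # weight on the short-term trace

    def __post_init__(self) -> None:
        vals = (self.alpha_super_short, self.alpha_short, self.alpha_raw_medium,
                self.alpha_mix, self.beta_mix)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("trace constants must lie in [0, 1]")
        if abs(self.alpha_mix + self.beta_mix - 1.0) > 1e-12:
            raise ValueError("alpha_mix + beta_mix must equal 1")


DEFAULT_TRACE_PARAMS = TraceParams()


class RunningAverages:
    """Per-unit cascaded activity traces (super-short, short, raw medium).

    ``medium`` — the linear mix of the raw medium and short traces — is the
    quantity entering coactivity.  Arrays have shape (batch, n_units).
    """

    __slots__ = ("params", "super_short", "short", "raw_medium")

    def __init__(self, batch: int, n_units: int,
                 params: TraceParams = DEFAULT_TRACE_PARAMS) -> None:
        self.params = params
        self.super_short = np.zeros((batch, n_units))
        self.short = np.zeros((batch, n_units))
        self.raw_medium = np.zeros((batch, n_units))

    def reset(self, activity: np.ndarray | float = 0.0) -> None:
        """Reset all traces to the given activity (a fresh trial)."""
        self.super_short[...] = activity
        self.short[...] = activity
        self.raw_medium[...] = activity

    def update(self, activity: np.ndarray) -> None:
        p = self.params
        self.super_short += p.alpha_super_short * (activity - self.super_short)
        self.short += p.alpha_short * (self.super_short - self.short)
        self.raw_medium += p.alpha_raw_medium * (self.short - self.raw_medium)

    @property
    def medium(self) -> np.ndarray:
        p = self.params
        return p.alpha_mix * self.raw_medium + p.beta_mix * self.short


def coactivity(medium_receiver: np.ndarray, medium_sender: np.ndarray) -> np.ndarray:
    """Pairwise coactivity: outer product of medium-term traces.

    Given (batch, n_recv) and (batch, n_send) arrays, returns
    (batch, n_send, n_recv) — symmetric in the sense that swapping the
    arguments transposes the unit axes.
    """
    mr = np.atleast_2d(medium_receiver)
    ms = np.atleast_2d(medium_sender)
    return ms[:, :, None] * mr[:, None, :]


def u_shape(kappa, params: UShapeParams) -> np.ndarray | float:
    """Raw weight change as a piecewise-linear U-shaped function of coactivity.

    Control points: (0, 0) — (d_thr, 0) — (d_rev, d_rev_mag) — (thr_p, 0) —
    (1, d_max_mag).  Not yet multiplied by the learning rate.
    """
    xp = np.array([0.0, params.d_thr, params.d_rev, params.thr_p, 1.0])
    fp = np.array([0.0, 0.0, params.d_rev_mag, 0.0, params.d_max_mag])
    out = np.interp(kappa, xp, fp)
    if np.isscalar(kappa):
        return float(out)
    return out


def weight_deltas(kappa: np.ndarray, ushape: UShapeParams) -> np.ndarray:
    """Learning-rate-scaled weight change for a coactivity array."""
    return ushape.lrate * u_shape(kappa, ushape)


def apply_weight_update(weights: np.ndarray, kappa: np.ndarray,
                        ushape: UShapeParams,
                        exclude_diagonal: bool = False) -> None:
    """In-place end-of-trial weight update with hard clipping to [0, 1].

    ``weights`` has shape (batch, n_send, n_recv); the single shared matrix of
    a bidirectional projection is updated exactly once per trial.  For
    recurrent projections the diagonal (self-connections) stays zero.
    """
    weights += weight_deltas(kappa, ushape)
    np.clip(weights, 0.0, 1.0, out=weights)
    if exclude_diagonal:
        n = weights.shape[-1]
        weights[:, np.arange(n), np.arange(n)] = 0.0
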