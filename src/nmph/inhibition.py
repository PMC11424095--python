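"""Tie-tolerant k-winners-take-all inhibition and inhibitory oscillations.

Inhibition within a layer is a single scalar conductance ``gi`` chosen every
cycle so that, at baseline, at most ``k`` units (or up to ``k_max`` when units
are tied with the k-th ranked unit within ``target_diff``) are above the
activation threshold.  During training trials, ``gi`` is modulated by one full
sine period over the last 75 cycles of the trial: raised above baseline first,
then lowered below baseline, which is what lets competitor units "pop up".
"""

from __future__ import annotations

import numpy as np

from .params import OSC_ONSET, OSC_PERIOD


def inhibition_thresholds(net_input: np.ndarray, threshold: float) -> np.ndarray:
    """Per-unit inhibition needed to put each unit exactly at activation
    threshold, sorted in descending order.

    With activity a monotone function of ``net - threshold - gi``, a unit is at
    threshold when ``gi = net - threshold``, so the ranking of these values is
    the ranking of net inputs.  Accepts a 1-D vector or a (batch, n) array;
    sorting is along the last axis.
    """
    g_thr = np.asarray(net_input, dtype=float) - threshold
    return -np.sort(-g_thr, axis=-1)


def kwta_inhibition(
    g_thr_ranked: np.ndarray,
    k: int,
    k_max: float,
    kwta_point: float,
    target_diff: float,
) -> np.ndarray | float:
    """Baseline layer inhibition from ranked threshold-inhibition values.

    The winner count ``k'`` starts at ``k`` and is extended over units ranked
    below the k-th whose threshold inhibition is within ``target_diff`` of the
    k-th unit's, capped at ``k_max``.  Inhibition is then placed a fraction
    ``kwta_point`` of the way from the k'-th unit's threshold value down
    toward the (k'+1)-th unit's, so higher ``kwta_point`` means lower
    inhibition.  If every unit wins, the (k'+1)-th reference is taken as 0.
    The result is clipped at 0 (inhibition is a non-negative conductance).

    Accepts a 1-D vector (returns a float) or a (batch, n) array (returns a
    (batch,) array).  Rows must be sorted in descending order.
    """
    g = np.atleast_2d(np.asarray(g_thr_ranked, dtype=float))
    n = g.shape[-1]
    if k >= n:
        raise ValueError(f"kWTA requires k < n_units (k={k}, n={n})")
    k_max_eff = int(min(k_max, n))

    # Extend winners over ties with the k-th ranked unit (cumulative AND keeps
    # the chain contiguous under float noise).
    kth = g[:, k - 1 : k]
    if k_max_eff > k:
        tied = (kth - g[:, k:k_max_eff]) <= target_diff
        extra = np.cumprod(tied, axis=1).sum(axis=1)
    else:
        extra = np.zeros(g.shape[0], dtype=int)
    k_eff = k + extra  # (batch,)

    rows = np.arange(g.shape[0])
    g_k = g[rows, k_eff - 1]
    g_next = np.where(k_eff < n, g[rows, np.minimum(k_eff, n - 1)], 0.0)
    gi = g_k - kwta_point * (g_k - g_next)
    gi = np.maximum(gi, 0.0)
    if np.ndim(g_thr_ranked) == 1:
        return float(gi[0])
    return gi


def oscillate_inhibition(gi_base, osc: float, cycle: float):
    """Sinusoidal modulation of baseline inhibition late in a trial.

    Inhibition is constant until cycle 125 (1-based), then multiplied by
    ``1 + osc * sin(2*pi*(cycle-125)/75)``: one full period over cycles
    125-200, above baseline through cycle ~163 and below baseline afterwards.
    """
    if cycle < OSC_ONSET or osc == 0.0:
        return gi_base
    phase = 2.0 * np.pi * (cycle - OSC_ONSET) / OSC_PERIOD
    return gi_base * (1.0 + osc * np.sin(phase))
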