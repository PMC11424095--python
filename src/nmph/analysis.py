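"""Representational-change metrics computed from test-epoch snapshots.

The central measures are the within-pair Pearson correlation of the two
pairmates' hidden-layer patterns (differentiation = decrease, integration =
increase relative to the baseline test epoch) and, for the topographic color
model, the center-of-mass of output activity (repulsion = centers moving
apart, attraction = moving together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Half-width of the no-change band around the baseline correlation used to
#: classify runs as differentiated / integrated / unchanged.
CLASSIFICATION_DELTA = 0.1

#: A pairmate whose hidden pattern moved less than this fraction of its
#: baseline norm counts as anchored when attributing asymmetry.
_ANCHOR_FRACTION = 0.05


def within_pair_correlation(pattern_a: np.ndarray, pattern_b: np.ndarray):
    """Pearson correlation of two activity patterns (vectorised over rows).

    Accepts 1-D vectors or (runs, n_units) arrays.  Zero-variance patterns
    yield NaN (flagged undefined, excluded from aggregates).
    """
    a = np.atleast_2d(np.asarray(pattern_a, dtype=float))
    b = np.atleast_2d(np.asarray(pattern_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("patterns must have equal shapes")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ac * bc).sum(axis=1) / denom, np.nan)
    return float(r[0]) if np.ndim(pattern_a) == 1 else r


def center_of_mass(pattern: np.ndarray):
    """Activity-weighted mean unit position; NaN for an all-zero pattern."""
    p = np.atleast_2d(np.asarray(pattern, dtype=float))
    total = p.sum(axis=1)
    idx = np.arange(p.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        com = np.where(total > 0, (p * idx).sum(axis=1) / total, np.nan)
    return float(com[0]) if np.ndim(pattern) == 1 else com


@dataclass
class RepulsionMetrics:
    """Center-of-mass repulsion/attraction measures for one set of runs.

    ``color_error_1/2`` are signed displacements of each pairmate's output
    center-of-mass, negative when directed away from the competitor.  Indices
    1/2 refer to presentation order, not to the A/B labels.
    """

    distance_change: np.ndarray
    color_error_1: np.ndarray
    color_error_2: np.ndarray


def repulsion_metrics(output_baseline_a, output_final_a,
                      output_baseline_b, output_final_b,
                      pairmate1) -> RepulsionMetrics:
    """Distance change between output centers-of-mass, plus per-pairmate
    signed color error (negative = away from the competitor).

    All pattern arguments are (runs, n_units); ``pairmate1`` is a (runs,)
    array of 0/1 flags naming the stimulus presented first.
    """
    com = {
        ("A", "base"): center_of_mass(output_baseline_a),
        ("A", "final"): center_of_mass(output_final_a),
        ("B", "base"): center_of_mass(output_baseline_b),
        ("B", "final"): center_of_mass(output_final_b),
    }
    dist_base = np.abs(com[("A", "base")] - com[("B", "base")])
    dist_final = np.abs(com[("A", "final")] - com[("B", "final")])

    # Signed error for each stimulus: positive = toward the competitor.
    toward = {}
    for me, other in (("A", "B"), ("B", "A")):
        direction = np.sign(com[(other, "base")] - com[(me, "base")])
        toward[me] = (com[(me, "final")] - com[(me, "base")]) * direction
    first_is_a = np.asarray(pairmate1) == 0
    err1 = np.where(first_is_a, toward["A"], toward["B"])
    err2 = np.where(first_is_a, toward["B"], toward["A"])
    return RepulsionMetrics(distance_change=dist_final - dist_base,
                            color_error_1=err1, color_error_2=err2)


@dataclass
class RunClassification:
    label: str            # 'differentiated' | 'integrated' | 'unchanged'
    onset_epoch: int | None
    asymmetry: str        # 'pairmate1' | 'pairmate2' | 'both' | 'neither'


def classify_run(correlations: np.ndarray,
                 hidden_a: np.ndarray | None = None,
                 hidden_b: np.ndarray | None = None,
                 pairmate1: int = 0,
                 delta: float = CLASSIFICATION_DELTA) -> RunClassification:
    """Classify one run's within-pair correlation time series.

    ``correlations`` includes the baseline at index 0.  The run is
    differentiated (integrated) if the final correlation lies more than
    ``delta`` below (above) baseline; the onset epoch is the first epoch
    leaving the band in the final direction.  If per-epoch hidden patterns
    (epochs+1, n_units) are supplied, asymmetry is attributed to the pairmate
    with the larger Euclidean displacement from its own baseline (at least
    twice the smaller one; 'both' otherwise, 'neither' if both anchored).
    """
    series = np.asarray(correlations, dtype=float)
    baseline = series[0]
    final = series[-1]
    if np.isnan(baseline) or np.isnan(final):
        label = "unchanged"
    elif final < baseline - delta:
        label = "differentiated"
    elif final > baseline + delta:
        label = "integrated"
    else:
        label = "unchanged"

    onset = None
    if label != "unchanged":
        sign = -1.0 if label == "differentiated" else 1.0
        crossed = sign * (series[1:] - baseline) > delta
        if crossed.any():
            onset = int(np.argmax(crossed)) + 1

    asymmetry = "neither"
    if hidden_a is not None and hidden_b is not None:
        moves, anchors = [], []
        for pat in (np.asarray(hidden_a), np.asarray(hidden_b)):
            moves.append(float(np.linalg.norm(pat[-1] - pat[0])))
            anchors.append(_ANCHOR_FRACTION * float(np.linalg.norm(pat[0])))
        # Reorder from (A, B) to presentation order (pairmate 1, pairmate 2).
        if pairmate1 == 1:
            moves = moves[::-1]
            anchors = anchors[::-1]
        moved = [m > a for m, a in zip(moves, anchors)]
        if not any(moved):
            asymmetry = "neither"
        elif moved[0] and (not moved[1] or moves[0] >= 2 * moves[1]):
            asymmetry = "pairmate1"
        elif moved[1] and (not moved[0] or moves[1] >= 2 * moves[0]):
            asymmetry = "pairmate2"
        else:
            asymmetry = "both"
    return RunClassification(label=label, onset_epoch=onset, asymmetry=asymmetry)


def correlation_series(result) -> np.ndarray:
    """Within-pair hidden correlation per test epoch, shape (epochs+1, runs)."""
    e = result.hidden.shape[0]
    return np.stack([
        within_pair_correlation(result.hidden[i, 0], result.hidden[i, 1])
        for i in range(e)
    ])


def classify_result(result, delta: float = CLASSIFICATION_DELTA) -> list[RunClassification]:
    """Per-run classification of an ExperimentResult."""
    series = correlation_series(result)
    out = []
    for run in range(result.n_runs):
        out.append(classify_run(
            series[:, run],
            hidden_a=result.hidden[:, 0, run],
            hidden_b=result.hidden[:, 1, run],
            pairmate1=int(result.pairmate1[run]),
            delta=delta,
        ))
    return out


def mds_embed_align(p1_before, p2_before, p1_after, p2_after):
    """Classical 2-D MDS of the four patterns of one run, aligned so that
    pairmate1-before sits at the origin and pairmate2-before on the +x axis
    at the baseline distance.

    Returns a (4, 2) array ordered (1_before, 2_before, 1_after, 2_after).
    """
    pats = np.stack([np.asarray(p, dtype=float)
                     for p in (p1_before, p2_before, p1_after, p2_after)])
    d = np.linalg.norm(pats[:, None, :] - pats[None, :, :], axis=-1)
    # Torgerson double centering.
    j = np.eye(4) - 0.25
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))

    coords = coords - coords[0]
    ref = coords[1]
    norm = np.linalg.norm(ref)
    if norm > 0:
        c, s = ref / norm
        rot = np.array([[c, s], [-s, c]])
        coords = coords @ rot.T
        if coords[3, 1] < 0:  # deterministic reflection: 2_after in upper half
            coords[:, 1] *= -1
    return coords


def aggregate_runs(values: np.ndarray, confidence: float = 0.95):
    """Mean and Student-t confidence interval over runs (NaN-excluded).

    ``values`` is 1-D (one value per run) or 2-D (epochs x runs, aggregated
    along the last axis).  Returns (mean, ci_low, ci_high).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n = np.sum(~np.isnan(v), axis=1)
    if np.any(n < 2):
        raise ValueError("aggregation requires at least two defined runs")
    mean = np.nanmean(v, axis=1)
    sem = np.nanstd(v, axis=1, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    lo, hi = mean - tcrit * sem, mean + tcrit * sem
    if np.ndim(values) == 1:
        return float(mean[0]), float(lo[0]), float(hi[0])
    return mean, lo, hi


def metrics_frame(result) -> pd.DataFrame:
    """Tidy per-run, per-epoch metrics table for one experiment result."""
    series = correlation_series(result)
    labels = classify_result(result)
    rows = []
    for run in range(result.n_runs):
        for epoch in range(series.shape[0]):
            rows.append({
                "run": run,
                "epoch": epoch,
                "study": result.config.study,
                "condition": result.config.condition,
                "correlation": series[epoch, run],
                "com_a": center_of_mass(result.output[epoch, 0, run]),
                "com_b": center_of_mass(result.output[epoch, 1, run]),
                "label": labels[run].label,
                "onset_epoch": labels[run].onset_epoch,
                "asymmetry": labels[run].asymmetry,
                "pairmate1": "AB"[int(result.pairmate1[run])],
            })
    return pd.DataFrame(rows)
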