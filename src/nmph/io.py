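"""Result serialization: tidy CSV tables plus a resolved-config JSON.

All outputs are plain text.  The snapshots table is the raw record (one row
per run, test epoch, stimulus, layer and unit); the metrics table carries the
derived per-run measures; the aggregate table the condition-level means with
confidence intervals.  Re-reading the CSVs reproduces the in-memory tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import aggregate_runs, correlation_series, metrics_frame
from .experiments import STIM_NAMES, ExperimentResult

SNAPSHOT_COLUMNS = ["run", "epoch", "phase", "stimulus", "layer", "unit_index",
                    "activity"]


def snapshots_frame(result: ExperimentResult) -> pd.DataFrame:
    """Tidy per-unit activity table of every test-epoch snapshot."""
    frames = []
    for layer_name, data in (("hidden", result.hidden), ("output", result.output)):
        e, _, b, n = data.shape
        epochs, stims, runs, units = np.meshgrid(
            np.arange(e), np.arange(2), np.arange(b), np.arange(n), indexing="ij")
        frames.append(pd.DataFrame({
            "run": runs.ravel(),
            "epoch": epochs.ravel(),
            "phase": "test",
            "stimulus": np.array(STIM_NAMES)[stims.ravel()],
            "layer": layer_name,
            "unit_index": units.ravel(),
            "activity": data.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)[SNAPSHOT_COLUMNS]


def aggregate_frame(result: ExperimentResult) -> pd.DataFrame:
    """Condition-level mean within-pair correlation per epoch with 95% CI."""
    series = correlation_series(result)
    mean, lo, hi = aggregate_runs(series)
    n_defined = np.sum(~np.isnan(series), axis=1)
    return pd.DataFrame({
        "study": result.config.study,
        "condition": str(result.config.condition),
        "epoch": np.arange(series.shape[0]),
        "mean_correlation": mean,
        "ci_low": lo,
        "ci_high": hi,
        "n_runs_defined": n_defined,
    })


def write_results(result: ExperimentResult, out_dir, resolved_config=None) -> dict[str, Path]:
    """Write snapshots, metrics and aggregate CSVs (and optionally the
    resolved-config JSON) into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snapshots": out / "snapshots.csv",
        "metrics": out / "metrics.csv",
        "aggregate": out / "aggregate.csv",
    }
    snapshots_frame(result).to_csv(paths["snapshots"], index=False)
    metrics_frame(result).to_csv(paths["metrics"], index=False)
    aggregate_frame(result).to_csv(paths["aggregate"], index=False)
    if resolved_config is not None:
        paths["config"] = out / "resolved_config.json"
        resolved_config.to_json(paths["config"])
    return paths


def read_snapshots(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"phase": str, "stimulus": str, "layer": str})
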