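"""Configuration loading, validation and resolution.

A resolved configuration is the complete parameter tree of one experiment:
the per-layer inhibitory/activity table, the per-projection weight and
U-shape tables, and the schedule settings.  Defaults come from the built-in
study tables; a YAML/JSON file or a dict of overrides adjusts them.  Unknown
keys are rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .experiments import ExperimentConfig
from .params import (
    LayerParams,
    ProjectionParams,
    UShapeParams,
    study_layers,
    study_projections,
)

_TOP_KEYS = {"study", "condition", "osc", "lrate", "n_runs", "n_epochs", "seed",
             "layers", "projections"}
_LAYER_KEYS = {f.name for f in dataclasses.fields(LayerParams)}
_PROJ_KEYS = {f.name for f in dataclasses.fields(ProjectionParams)} | {"ushape"}
_USHAPE_KEYS = {f.name for f in dataclasses.fields(UShapeParams)}


class ConfigError(ValueError):
    """A configuration file or override violates the schema."""


@dataclass(frozen=True)
class ResolvedConfig:
    """Fully resolved experiment settings (defaults + overrides applied)."""

    experiment: ExperimentConfig
    layers: dict[str, LayerParams]
    projections: list[ProjectionParams]

    def to_dict(self) -> dict:
        d = {
            "study": self.experiment.study,
            "condition": self.experiment.condition,
            "osc": self.experiment.osc,
            "lrate": self.experiment.lrate,
            "n_runs": self.experiment.n_runs,
            "n_epochs": self.experiment.n_epochs,
            "seed": self.experiment.seed,
            "layers": {name: asdict(sp) for name, sp in self.layers.items()},
            "projections": [asdict(sp) for sp in self.projections],
        }
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         default=_json_default) + "\n")


def _json_default(obj):
    if obj == float("inf"):
        return "inf"
    raise TypeError(f"not JSON serializable: {obj!r}")


def _check_keys(given: dict, allowed: set[str], context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {key!r} in {context} "
                          f"(allowed: {', '.join(sorted(allowed))})")


def resolve_config(study: str, condition, overrides: dict | None = None) -> ResolvedConfig:
    """Build a resolved configuration from study defaults plus overrides.

    ``overrides`` may adjust top-level schedule fields (``n_runs``,
    ``n_epochs``, ``seed``, ``osc``, ``lrate``) and any per-layer or
    per-projection parameter via nested mappings, e.g.::

        {"n_runs": 10, "layers": {"hidden": {"osc": 0.09}},
         "projections": {"hidden->hidden": {"ushape": {"lrate": 0.5}}}}
    """
    overrides = dict(overrides or {})
    _check_keys(overrides, _TOP_KEYS, "configuration")
    overrides.setdefault("study", study)
    overrides.setdefault("condition", condition)
    if overrides["study"] != study or overrides["condition"] != condition:
        raise ConfigError("study/condition in overrides conflict with arguments")

    layer_over = overrides.pop("layers", {}) or {}
    proj_over = overrides.pop("projections", {}) or {}
    exp = ExperimentConfig(
        study=study,
        condition=condition,
        osc=overrides.get("osc"),
        lrate=overrides.get("lrate"),
        n_runs=int(overrides.get("n_runs", 50)),
        n_epochs=int(overrides.get("n_epochs", 20)),
        seed=int(overrides.get("seed", 0)),
    )

    layers = study_layers(study, hidden_osc=exp.osc)
    for name, over in layer_over.items():
        if name not in layers:
            raise ConfigError(f"unknown layer {name!r} "
                              f"(layers: {', '.join(layers)})")
        _check_keys(over, _LAYER_KEYS - {"name", "n_units"}, f"layer {name!r}")
        layers[name] = dataclasses.replace(layers[name], **over)

    projections = study_projections(study, lrate=exp.lrate)
    by_key = {f"{p.sender}->{p.receiver}": i for i, p in enumerate(projections)}
    for key, over in proj_over.items():
        if key not in by_key:
            raise ConfigError(f"unknown projection {key!r} "
                              f"(projections: {', '.join(by_key)})")
        over = dict(over)
        _check_keys(over, _PROJ_KEYS - {"sender", "receiver"}, f"projection {key!r}")
        ushape_over = over.pop("ushape", None)
        i = by_key[key]
        proj = dataclasses.replace(projections[i], **over)
        if ushape_over:
            _check_keys(ushape_over, _USHAPE_KEYS, f"ushape of {key!r}")
            proj = dataclasses.replace(
                proj, ushape=dataclasses.replace(proj.ushape, **ushape_over))
        projections[i] = proj
    return ResolvedConfig(experiment=exp, layers=layers, projections=projections)


def load_config(path) -> ResolvedConfig:
    """Load and validate a YAML (or JSON) experiment configuration file.

    The file must name ``study`` and ``condition``; all other keys are
    optional overrides on the study defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got "
                          f"{type(data).__name__}")
    if "study" not in data or "condition" not in data:
        raise ConfigError("configuration must set 'study' and 'condition'")
    study = data["study"]
    condition = data["condition"]
    overrides = {k: v for k, v in data.items()}
    return resolve_config(study, condition, overrides)
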