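"""YAML (de)serialization for model specifications and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from . import __version__
from .effects import EffectSpec, ModelSpec


def model_to_dict(model: ModelSpec) -> dict:
    return {
        "n_periods": model.n_periods,
        "behavior_ranges": {s: list(r) for s, r in model.behavior_ranges.items()},
        "rates": {dep: [float(v) for v in vals]
                  for dep, vals in model.rates.items()},
        "effects": [
            {k: v for k, v in {
                "name": e.name,
                "dependent": e.dependent,
                "phase": e.phase,
                "attribute_ref": e.attribute_ref,
                "beta": float(e.beta),
            }.items() if not (k == "attribute_ref" and v is None)}
            for e in model.effects
        ],
        "centering": {
            "behavior_means": dict(model.behavior_means),
            "covariate_means": dict(model.covariate_means),
            "covariate_ranges": dict(model.covariate_ranges),
            "similarity_means": dict(model.similarity_means),
        },
    }


def model_from_dict(data: dict) -> ModelSpec:
    try:
        effects = [EffectSpec(
            name=e["name"],
            dependent=e["dependent"],
            phase=e.get("phase", "evaluation"),
            attribute_ref=e.get("attribute_ref"),
            beta=float(e.get("beta", 0.0)),
        ) for e in data["effects"]]
        model = ModelSpec(
            effects=effects,
            rates={dep: [float(v) for v in vals]
                   for dep, vals in data["rates"].items()},
            behavior_ranges={s: tuple(r)
                             for s, r in data["behavior_ranges"].items()},
            n_periods=int(data.get("n_periods", 2)),
        )
    except KeyError as exc:
        raise KeyError(f"missing config key: {exc.args[0]}") from exc
    centering = data.get("centering", {})
    model.behavior_means = dict(centering.get("behavior_means", {}))
    model.covariate_means = dict(centering.get("covariate_means", {}))
    model.covariate_ranges = dict(centering.get("covariate_ranges", {}))
    model.similarity_means = dict(centering.get("similarity_means", {}))
    model.validate()
    return model


def save_model(model: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model),
                                         sort_keys=False))


def load_model(path: str | Path) -> ModelSpec:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(directory: str | Path, command: str, seed: int | None,
                   config: dict | None = None) -> Path:
    """Record the seed/config/version of a run so it can be replayed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
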