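"""Model configuration files and result serialization.

The model config is a YAML document:

.. code-block:: yaml

    acp_total: 69.5
    fixed:
      acetyl_coa: 100.0
      g3p: 200.0
      c16_1_acp: 1.0
      ppgpp: 0.0
    reactions:
      ACC:
        vmax: 96.3
        km_a: 50.0
        km_b: 10.0
        inhibitors:
          - {species: c16_acp, ki: 0.1}
          - {species: c18_acp, ki: 0.1}
      PLSB_C16:
        vmax: 58.5
        km_a: 50.0
        km_b: 100.0
        ki_ppgpp: 10.0
      # ... one block per reaction

Round trips are lossless; unknown keys are rejected with an error naming
the offending key. Exports are UTF-8, Unix-newline TSV (12 significant
digits) and JSON summaries that carry a provenance record (config hash,
seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    REACTIONS,
    ConfigurationError,
    FixedInputs,
    Inhibitor,
    PathwayModel,
    ReactionKinetics,
)

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "parse_model_config",
    "write_model_config",
    "export_table",
    "export_json",
    "provenance",
]

_FIXED_KEYS = ("acetyl_coa", "g3p", "c16_1_acp", "ppgpp")
_REACTION_KEYS = {"vmax", "km_a", "km_b", "inhibitors", "ki_ppgpp"}


def model_to_dict(model: PathwayModel) -> dict:
    reactions = {}
    for k in model.kinetics:
        block: dict = {"vmax": float(k.vmax), "km_a": float(k.km_a)}
        if k.km_b is not None:
            block["km_b"] = float(k.km_b)
        if k.inhibitors:
            block["inhibitors"] = [
                {"species": i.species, "ki": float(i.ki)} for i in k.inhibitors
            ]
        if k.ki_ppgpp is not None:
            block["ki_ppgpp"] = float(k.ki_ppgpp)
        reactions[k.reaction_id] = block
    return {
        "acp_total": float(model.acp_total),
        "fixed": {key: float(getattr(model.fixed, key)) for key in _FIXED_KEYS},
        "reactions": reactions,
    }


def model_from_dict(doc: dict) -> PathwayModel:
    if not isinstance(doc, dict):
        raise ConfigurationError("model config must be a mapping")
    unknown = set(doc) - {"acp_total", "fixed", "reactions"}
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    if "reactions" not in doc:
        raise ConfigurationError("model config is missing 'reactions'")
    fixed_doc = doc.get("fixed", {})
    bad = set(fixed_doc) - set(_FIXED_KEYS)
    if bad:
        raise ConfigurationError(f"unknown fixed-input keys: {sorted(bad)}")
    fixed = FixedInputs(**{k: float(v) for k, v in fixed_doc.items()})

    kinetics = []
    for rid, block in doc["reactions"].items():
        if rid not in REACTIONS:
            raise ConfigurationError(f"unknown reaction id {rid!r}")
        if not isinstance(block, dict):
            raise ConfigurationError(f"{rid}: reaction block must be a mapping")
        bad = set(block) - _REACTION_KEYS
        if bad:
            raise ConfigurationError(f"{rid}: unknown keys {sorted(bad)}")
        for req in ("vmax", "km_a"):
            if req not in block:
                raise ConfigurationError(f"{rid}: missing required key {req!r}")
        inhibitors = tuple(
            Inhibitor(species=str(i["species"]), ki=float(i["ki"]))
            for i in block.get("inhibitors", ())
        )
        try:
            kinetics.append(
                ReactionKinetics(
                    reaction_id=rid,
                    vmax=float(block["vmax"]),
                    km_a=float(block["km_a"]),
                    km_b=None if block.get("km_b") is None else float(block["km_b"]),
                    inhibitors=inhibitors,
                    ki_ppgpp=(
                        None
                        if block.get("ki_ppgpp") is None
                        else float(block["ki_ppgpp"])
                    ),
                )
            )
        except ValueError as exc:
            raise ConfigurationError(f"{rid}: {exc}") from exc
    acp_total = float(doc.get("acp_total", 0.0))
    if acp_total <= 0:
        raise ConfigurationError("acp_total must be a positive concentration")
    return PathwayModel(kinetics=tuple(kinetics), fixed=fixed, acp_total=acp_total)


def parse_model_config(path) -> PathwayModel:
    """Load and validate a YAML model definition."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def write_model_config(model: PathwayModel, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Reproducibility record attached to every JSON export."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "package": "lipidflux",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def _format_float(x) -> str:
    return f"{x:.12g}"


def export_table(frame: pd.DataFrame, path) -> Path:
    """Write a TSV with deterministic column order and 12-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(
        path,
        sep="\t",
        index=False,
        float_format="%.12g",
        lineterminator="\n",
        encoding="utf-8",
    )
    return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    return obj


def export_json(payload: dict, path, seed: int | None = None, config: dict | None = None) -> Path:
    """Write a JSON summary including the provenance record."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"provenance": provenance(seed=seed, config=config)}
    doc.update(_jsonify(payload))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return path
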