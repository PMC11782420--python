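"""YAML configuration for entities, Golgi geometry, enzymes and kinetic
parameters.

Schema (all sections optional; omitted sections fall back to the fixture
defaults)::

    entities:
      - {name: IgG, molecular_weight: 150.0, production_rate: 0.1}
    golgi:
      residence_time_ref: [5.0, 5.0, 5.0, 5.0]
      mw_ref: 150.0
    enzymes:
      ManI: {law: MM, fractions: [0.85, 0.15, 0.0, 0.0]}
      GnTI: {law: BiBi, nsd: UDP-GlcNAc, fractions: [0.05, 0.6, 0.35, 0.0]}
    params:
      kf: {ManI: 887.0}
      enz_total: {ManI: 0.29}
      nsd_conc: {UDP-GlcNAc: 7600.0}
      km: {"ManI:IgG": 100.0}       # "enzyme:entity" or "node:enzyme:entity"
      kmd: {GnTI: 170.0}
      m9_prop: {IgG: 0.2}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .fixtures import default_entities, default_parameters
from .kinetics import EnzymeSpec, GolgiConfig, KineticParameterSet, ProteinEntity, default_enzyme_specs

__all__ = ["load_config", "dump_config", "default_config"]


def _parse_km_key(key: str):
    parts = key.split(":")
    if len(parts) == 2:
        return (parts[0], parts[1])
    if len(parts) == 3:
        return (parts[0], parts[1], parts[2])
    raise ValueError(f"km key must be 'enzyme:entity' or 'node:enzyme:entity', got {key!r}")


def load_config(path) -> dict:
    """Load a YAML config into model objects.

    Returns ``{"entities": [...], "golgi": GolgiConfig, "enzymes": {...},
    "params": KineticParameterSet}``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}

    if "entities" in raw:
        entities = [
            ProteinEntity(
                name=e["name"],
                molecular_weight=float(e["molecular_weight"]),
                production_rate=float(e.get("production_rate", 0.1)),
            )
            for e in raw["entities"]
        ]
    else:
        entities = default_entities()

    if "golgi" in raw:
        g = raw["golgi"]
        golgi = GolgiConfig(
            residence_time_ref=tuple(g.get("residence_time_ref", (5.0, 5.0, 5.0, 5.0))),
            mw_ref=float(g.get("mw_ref", 150.0)),
        )
    else:
        golgi = GolgiConfig()

    enzymes = default_enzyme_specs()
    for name, spec in (raw.get("enzymes") or {}).items():
        enzymes[name] = EnzymeSpec(
            name=name,
            law=spec.get("law", enzymes[name].law if name in enzymes else "BiBi"),
            nsd=spec.get("nsd", enzymes[name].nsd if name in enzymes else None),
            compartment_fractions=tuple(
                spec.get(
                    "fractions",
                    enzymes[name].compartment_fractions if name in enzymes else (0.25,) * 4,
                )
            ),
        )

    params = default_parameters(entities)
    p = raw.get("params") or {}
    for section in ("kf", "enz_total", "nsd_conc", "kmd", "m9_prop"):
        for key, value in (p.get(section) or {}).items():
            getattr(params, section)[key] = float(value)
    for key, value in (p.get("km") or {}).items():
        params.km[_parse_km_key(key)] = float(value)

    return {"entities": entities, "golgi": golgi, "enzymes": enzymes, "params": params}


def default_config() -> dict:
    return {
        "entities": default_entities(),
        "golgi": GolgiConfig(),
        "enzymes": default_enzyme_specs(),
        "params": default_parameters(),
    }


def dump_config(config: dict, path) -> None:
    """Write a config dict (as returned by :func:`load_config`) to YAML."""
    params: KineticParameterSet = config["params"]
    km = {}
    for key, value in params.km.items():
        km[":".join(key)] = value
    payload = {
        "entities": [
            {
                "name": e.name,
                "molecular_weight": e.molecular_weight,
                "production_rate": e.production_rate,
            }
            for e in config["entities"]
        ],
        "golgi": {
            "residence_time_ref": list(config["golgi"].residence_time_ref),
            "mw_ref": config["golgi"].mw_ref,
        },
        "enzymes": {
            name: {
                "law": spec.law,
                **({"nsd": spec.nsd} if spec.nsd else {}),
                "fractions": list(spec.compartment_fractions),
            }
            for name, spec in config["enzymes"].items()
        },
        "params": {
            "kf": dict(params.kf),
            "enz_total": dict(params.enz_total),
            "nsd_conc": dict(params.nsd_conc),
            "km": km,
            "kmd": dict(params.kmd),
            "m9_prop": dict(params.m9_prop),
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
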