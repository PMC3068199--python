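"""Native structured-text (YAML) model format.

One document with sections ``species`` / ``reactions`` / ``rules`` /
``events`` / ``parameters`` plus ``name`` and the optional ``stimulus``
designation.  The schema is deliberately flat so a model is diffable and
hand-editable; see README for the full schema.
"""

from __future__ import annotations

import io
from pathlib import Path

import yaml

from .model import (
    AssignmentRule,
    Event,
    KineticLaw,
    Parameter,
    Reaction,
    ReactionModel,
    SpeciesDef,
)

__all__ = ["model_to_dict", "model_from_dict", "dump_model", "load_model"]


def model_to_dict(model: ReactionModel) -> dict:
    d: dict = {
        "name": model.name,
        "species": [
            {"id": s.id, "role": s.role, "initial": float(s.initial_value)}
            for s in model.species
        ],
        "reactions": [
            {
                "id": r.id,
                "substrates": list(r.substrates),
                "products": list(r.products),
                "kinetics": {
                    "template": r.law.template,
                    "parameters": list(r.law.parameter_ids),
                    "modifiers": [
                        {"species": sid, "role": role} for sid, role in r.law.modifiers
                    ],
                },
            }
            for r in model.reactions
        ],
        "rules": [{"target": r.target, "expression": r.expression} for r in model.rules],
        "events": [
            {"time": float(e.time), "target": e.target, "amount": float(e.amount)}
            for e in model.events
        ],
        "parameters": [
            {"id": p.id, "value": float(p.value), "lower": float(p.lower), "upper": float(p.upper)}
            for p in model.parameters.values()
        ],
    }
    if model.stimulus is not None:
        d["stimulus"] = model.stimulus
    return d


def model_from_dict(d: dict) -> ReactionModel:
    species = [
        SpeciesDef(id=s["id"], role=s.get("role", "dynamic"), initial_value=float(s.get("initial", 0.0)))
        for s in d.get("species", [])
    ]
    reactions = []
    for r in d.get("reactions", []):
        kin = r["kinetics"]
        law = KineticLaw(
            template=kin["template"],
            parameter_ids=list(kin["parameters"]),
            modifiers=[(m["species"], m["role"]) for m in kin.get("modifiers", [])],
        )
        reactions.append(
            Reaction(
                id=r["id"],
                substrates=list(r.get("substrates", [])),
                products=list(r.get("products", [])),
                law=law,
            )
        )
    rules = [AssignmentRule(x["target"], x["expression"]) for x in d.get("rules", [])]
    events = [Event(float(x["time"]), x["target"], float(x["amount"])) for x in d.get("events", [])]
    params = {
        p["id"]: Parameter(
            id=p["id"],
            value=float(p.get("value", 1.0)),
            lower=float(p.get("lower", 1e-6)),
            upper=float(p.get("upper", 1e3)),
        )
        for p in d.get("parameters", [])
    }
    return ReactionModel(
        name=d.get("name", "model"),
        species=species,
        reactions=reactions,
        rules=rules,
        events=events,
        parameters=params,
        stimulus=d.get("stimulus"),
    )


def dump_model(model: ReactionModel, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(model_to_dict(model), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_model(source: str | Path) -> ReactionModel:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    return model_from_dict(yaml.safe_load(io.StringIO(text)))
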