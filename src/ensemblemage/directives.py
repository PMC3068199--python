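"""Candidate model generation from a master model via declarative directives.

A candidate is described only by how it differs from the master: species and
reactions to delete, kinetic templates to swap in, modifiers to rebind, and
which species drives pathway stimulation.  Applying a directive set cascades
consistently (reactions touching a deleted species go with it, orphaned
parameters are swept) and produces a provenance record stating exactly what
was done, so every candidate — including unsuccessful ones — stays traceable
to the master.

Directive kinds
---------------
``delete_species``       remove a species; cascades to every reaction having
                         it as substrate or product; a reaction left with a
                         dangling *modifier* is an error unless a
                         ``substitute_modifier`` directive covers it.
``delete_reaction``      remove one reaction.
``swap_kinetics``        replace a reaction's rate law template; fresh
                         parameters are minted per the template, modifiers
                         not used by the new template are dropped.
``substitute_modifier``  rebind a reaction's modifier old -> new species.
``set_input``            designate the species that drives stimulation:
                         every modifier reference to the current stimulus is
                         rebound to the named species.

Directive order within a set is normalised (rebindings and swaps first,
reaction deletions, then species deletions) so sets are declarative.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io_native import dump_model
from .model import KineticLaw, Parameter, ReactionModel, validate_model

__all__ = [
    "Directive",
    "CandidateSpec",
    "ProvenanceRecord",
    "DirectiveError",
    "apply_directives",
    "generate_ensemble",
    "write_provenance",
    "load_candidate_specs",
    "dump_candidate_specs",
]

_KINDS = ("delete_species", "delete_reaction", "swap_kinetics", "substitute_modifier", "set_input")

#: parameter id stems minted when a kinetic template is swapped in
_PARAM_STEMS = {
    "mass_action": ("k",),
    "michaelis_menten": ("Vmax", "Km"),
    "zero_order": ("v0",),
    "regulated_efflux": ("Vmax", "Km", "Ki"),
}


class DirectiveError(ValueError):
    """A directive references a missing element or leaves the model broken."""


@dataclass
class Directive:
    kind: str
    target: str | None = None          # species or reaction id
    new_template: str | None = None    # swap_kinetics
    old_species: str | None = None     # substitute_modifier
    new_species: str | None = None     # substitute_modifier / set_input

    def describe(self) -> str:
        if self.kind == "delete_species":
            return f"delete species {self.target}"
        if self.kind == "delete_reaction":
            return f"delete reaction {self.target}"
        if self.kind == "swap_kinetics":
            return f"swap kinetics of {self.target} to {self.new_template}"
        if self.kind == "substitute_modifier":
            where = self.target or "all reactions"
            return f"substitute modifier {self.old_species} -> {self.new_species} in {where}"
        if self.kind == "set_input":
            return f"set input (stimulus) species to {self.new_species}"
        return f"unknown directive {self.kind}"


@dataclass
class CandidateSpec:
    name: str
    directives: list[Directive]

    @staticmethod
    def from_dict(name: str, items: list[dict]) -> "CandidateSpec":
        dirs = []
        for it in items:
            kind = it["kind"]
            if kind not in _KINDS:
                raise DirectiveError(f"candidate {name}: unknown directive kind {kind!r}")
            dirs.append(
                Directive(
                    kind=kind,
                    target=it.get("target"),
                    new_template=it.get("new_template"),
                    old_species=it.get("old_species"),
                    new_species=it.get("new_species"),
                )
            )
        return CandidateSpec(name=name, directives=dirs)

    def to_list(self) -> list[dict]:
        out = []
        for d in self.directives:
            item = {"kind": d.kind}
            for k in ("target", "new_template", "old_species", "new_species"):
                v = getattr(d, k)
                if v is not None:
                    item[k] = v
            out.append(item)
        return out


@dataclass
class ProvenanceRecord:
    candidate: str
    master: str
    master_hash: str
    directives: list[str]
    cascade_deleted_reactions: list[str] = field(default_factory=list)
    removed_parameters: list[str] = field(default_factory=list)
    removed_rules: list[str] = field(default_factory=list)
    removed_events: int = 0
    n_species: int = 0
    n_reactions: int = 0
    n_parameters: int = 0

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "master": self.master,
            "master_hash": self.master_hash,
            "directives": list(self.directives),
            "cascade_deleted_reactions": list(self.cascade_deleted_reactions),
            "removed_parameters": list(self.removed_parameters),
            "removed_rules": list(self.removed_rules),
            "removed_events": self.removed_events,
            "counts": {
                "species": self.n_species,
                "reactions": self.n_reactions,
                "parameters": self.n_parameters,
            },
        }


def _normalised(directives: list[Directive]) -> list[Directive]:
    order = {
        "set_input": 0,
        "substitute_modifier": 1,
        "swap_kinetics": 2,
        "delete_reaction": 3,
        "delete_species": 4,
    }
    return sorted(directives, key=lambda d: order.get(d.kind, 99))


def master_hash(master: ReactionModel) -> str:
    return hashlib.sha256(dump_model(master).encode()).hexdigest()[:16]


def apply_directives(
    master: ReactionModel, spec: CandidateSpec
) -> tuple[ReactionModel, ProvenanceRecord]:
    """Derive a candidate from the master and document how.

    Raises :class:`DirectiveError` on a directive targeting a missing element,
    on a substitution to a species that does not survive the candidate's own
    deletions, or on a modifier left dangling by a species deletion.
    """
    model = master.copy()
    model.name = spec.name
    rec = ProvenanceRecord(
        candidate=spec.name,
        master=master.name,
        master_hash=master_hash(master),
        directives=[d.describe() for d in _normalised(spec.directives)],
    )
    deleted_species = {
        d.target for d in spec.directives if d.kind == "delete_species"
    }

    for d in _normalised(spec.directives):
        if d.kind == "set_input":
            if d.new_species not in model.species_ids():
                raise DirectiveError(
                    f"{spec.name}: set_input target {d.new_species} does not exist"
                )
            old = model.stimulus
            if old is None:
                raise DirectiveError(f"{spec.name}: master has no stimulus species to rebind")
            for rxn in model.reactions:
                rxn.law.modifiers = [
                    (d.new_species if sid == old else sid, role)
                    for sid, role in rxn.law.modifiers
                ]
            model.stimulus = d.new_species

        elif d.kind == "substitute_modifier":
            if d.new_species in deleted_species:
                raise DirectiveError(
                    f"{spec.name}: substitute_modifier to {d.new_species}, "
                    "which is deleted by the same candidate"
                )
            if d.new_species not in model.species_ids():
                raise DirectiveError(
                    f"{spec.name}: substitute_modifier target species {d.new_species} does not exist"
                )
            if d.target and d.target not in [r.id for r in model.reactions]:
                raise DirectiveError(f"{spec.name}: no reaction {d.target}")
            targets = [model.get_reaction(d.target)] if d.target else model.reactions
            hit = False
            for rxn in targets:
                new_mods = []
                for sid, role in rxn.law.modifiers:
                    if sid == d.old_species:
                        hit = True
                        new_mods.append((d.new_species, role))
                    else:
                        new_mods.append((sid, role))
                rxn.law.modifiers = new_mods
            if not hit:
                raise DirectiveError(
                    f"{spec.name}: modifier {d.old_species} not found"
                    + (f" in reaction {d.target}" if d.target else "")
                )

        elif d.kind == "swap_kinetics":
            try:
                rxn = model.get_reaction(d.target)
            except KeyError:
                raise DirectiveError(f"{spec.name}: swap_kinetics on missing reaction {d.target}")
            stems = _PARAM_STEMS.get(d.new_template)
            if stems is None:
                raise DirectiveError(f"{spec.name}: unknown kinetic template {d.new_template}")
            bounds = [
                (model.parameters[p].lower, model.parameters[p].upper)
                for p in rxn.law.parameter_ids
            ]
            lo, hi = bounds[0] if bounds else (1e-6, 1e3)
            new_pids = [f"{stem}_{rxn.id}" for stem in stems]
            # keep only the modifier roles the new template uses
            keep_roles = {"catalyst"}
            if d.new_template == "regulated_efflux":
                keep_roles = {"catalyst", "inhibitor"}
            elif d.new_template == "zero_order":
                keep_roles = set()
            rxn.law = KineticLaw(
                template=d.new_template,
                parameter_ids=new_pids,
                modifiers=[(s, r) for s, r in rxn.law.modifiers if r in keep_roles],
            )
            for pid in new_pids:
                model.parameters.setdefault(pid, Parameter(id=pid, value=1.0, lower=lo, upper=hi))

        elif d.kind == "delete_reaction":
            if d.target not in [r.id for r in model.reactions]:
                raise DirectiveError(f"{spec.name}: delete_reaction on missing reaction {d.target}")
            model.reactions = [r for r in model.reactions if r.id != d.target]

        elif d.kind == "delete_species":
            if d.target not in model.species_ids():
                raise DirectiveError(f"{spec.name}: delete_species on missing species {d.target}")
            sid = d.target
            cascade = [r.id for r in model.reactions if sid in r.substrates or sid in r.products]
            rec.cascade_deleted_reactions.extend(cascade)
            model.reactions = [r for r in model.reactions if r.id not in cascade]
            for rule in model.rules:
                if rule.target == sid or sid in {str(s) for s in rule.as_sympy().free_symbols}:
                    rec.removed_rules.append(rule.target)
            model.rules = [r for r in model.rules if r.target not in rec.removed_rules]
            before = len(model.events)
            model.events = [e for e in model.events if e.target != sid]
            rec.removed_events += before - len(model.events)
            model.species = [s for s in model.species if s.id != sid]
            if model.stimulus == sid:
                model.stimulus = None
        else:
            raise DirectiveError(f"{spec.name}: unknown directive kind {d.kind}")

    # modifiers left dangling by species deletions: error, never silent dropping
    # (rewired catalysis changes model meaning, so it must be explicit)
    surviving = set(model.species_ids())
    dangling = [
        f"{r.id} (modifier {sid})"
        for r in model.reactions
        for sid, _role in r.law.modifiers
        if sid not in surviving
    ]
    if dangling:
        raise DirectiveError(
            f"{spec.name}: dangling modifier after deletions in "
            f"{', '.join(dangling)}; add a substitute_modifier directive"
        )

    # sweep parameters no longer referenced by any kinetic law
    used = {pid for r in model.reactions for pid in r.law.parameter_ids}
    rec.removed_parameters = sorted(set(model.parameters) - used)
    model.parameters = {pid: p for pid, p in model.parameters.items() if pid in used}

    problems = validate_model(model)
    if problems:
        raise DirectiveError(f"{spec.name}: derived model invalid: " + "; ".join(problems))
    rec.n_species = len(model.species)
    rec.n_reactions = len(model.reactions)
    rec.n_parameters = len(model.parameters)
    return model, rec


def generate_ensemble(
    master: ReactionModel, specs: list[CandidateSpec]
) -> tuple[list[tuple[ReactionModel, ProvenanceRecord]], dict[str, str]]:
    """Apply every candidate spec; one bad spec does not abort the others.

    Returns ``(results, errors)`` where ``errors`` maps candidate name to the
    failure message.  Duplicate candidate names are an error up front.
    """
    names = [s.name for s in specs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DirectiveError(f"duplicate candidate names: {dupes}")
    results, errors = [], {}
    for spec in specs:
        try:
            results.append(apply_directives(master, spec))
        except DirectiveError as exc:
            errors[spec.name] = str(exc)
    return results, errors


def write_provenance(
    records: list[ProvenanceRecord], out_dir: str | Path | None = None
) -> tuple[str, str]:
    """Render provenance as a markdown report plus a machine-readable JSON twin."""
    lines = ["# Candidate provenance", ""]
    for rec in records:
        lines.append(f"## {rec.candidate}")
        lines.append(f"Derived from master `{rec.master}` (hash `{rec.master_hash}`).")
        lines.append("")
        lines.append("Directives applied:")
        for d in rec.directives:
            lines.append(f"- {d}")
        if rec.cascade_deleted_reactions:
            lines.append(
                "Cascade: reactions deleted with their species: "
                + ", ".join(rec.cascade_deleted_reactions)
            )
        if rec.removed_rules:
            lines.append("Assignment rules removed: " + ", ".join(sorted(set(rec.removed_rules))))
        if rec.removed_parameters:
            lines.append("Orphaned parameters swept: " + ", ".join(rec.removed_parameters))
        lines.append(
            f"Result: {rec.n_species} species, {rec.n_reactions} reactions, "
            f"{rec.n_parameters} parameters."
        )
        lines.append("")
    md = "\n".join(lines)
    js = json.dumps([r.to_dict() for r in records], indent=2)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "provenance.md").write_text(md)
        (out / "provenance.json").write_text(js)
    return md, js


# ---------------------------------------------------------------------------
# ensemble file format: one YAML document, keys = candidate names
# ---------------------------------------------------------------------------

def load_candidate_specs(source: str | Path) -> list[CandidateSpec]:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    data = yaml.safe_load(text)
    return [CandidateSpec.from_dict(name, items) for name, items in data.items()]


def dump_candidate_specs(specs: list[CandidateSpec], path: str | Path | None = None) -> str:
    data = {s.name: s.to_list() for s in specs}
    text = yaml.safe_dump(data, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
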