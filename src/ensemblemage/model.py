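"""Declarative reaction-network models with templated kinetics.

A :class:`ReactionModel` holds species, reactions whose rate laws are drawn
from a small set of kinetic templates, assignment rules for derived species,
timed addition events, and a parameter table with fitting bounds.  The model
compiles to an ODE right-hand side via sympy, so the same declarative object
drives validation, simulation, stoichiometric analysis and SBML export.

Kinetic templates (S = substrate, M = catalyst modifier, I = inhibitor
modifier; p1, p2, p3 the law's parameters in order):

``mass_action``        rate = p1 * prod(S) * [M]   (catalyst optional,
                       substrate-less production reactions allowed)
``michaelis_menten``   rate = p1 * [M] * [S] / (p2 + [S])   (M optional)
``zero_order``         rate = p1
``regulated_efflux``   rate = p1 * [S] / (p2 + [S]) * p3 / (p3 + [I])
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

__all__ = [
    "SpeciesDef",
    "KineticLaw",
    "Reaction",
    "Parameter",
    "AssignmentRule",
    "Event",
    "ReactionModel",
    "KINETIC_TEMPLATES",
    "validate_model",
    "build_rhs",
    "conserved_moieties",
    "stoichiometry_matrix",
]

ROLES = ("dynamic", "input", "derived")

#: template name -> number of parameters
KINETIC_TEMPLATES = {
    "mass_action": 1,
    "michaelis_menten": 2,
    "zero_order": 1,
    "regulated_efflux": 3,
}


@dataclass
class SpeciesDef:
    """A model component.

    role ``dynamic``: governed by an ODE; ``input``: externally driven
    (zero derivative between events); ``derived``: defined by an
    assignment rule, no ODE.  Protein species are fractions of their
    conserved total; osmolyte species are in M.
    """

    id: str
    role: str = "dynamic"
    initial_value: float = 0.0


@dataclass
class KineticLaw:
    template: str
    parameter_ids: list[str]
    #: list of (species_id, role) with role in {"catalyst", "inhibitor"}
    modifiers: list[tuple[str, str]] = field(default_factory=list)

    @property
    def catalyst(self) -> str | None:
        for sid, role in self.modifiers:
            if role == "catalyst":
                return sid
        return None

    @property
    def inhibitor(self) -> str | None:
        for sid, role in self.modifiers:
            if role == "inhibitor":
                return sid
        return None


@dataclass
class Reaction:
    id: str
    substrates: list[str]
    products: list[str]
    law: KineticLaw


@dataclass
class Parameter:
    id: str
    value: float = 1.0
    lower: float = 1e-6
    upper: float = 1e3


@dataclass
class AssignmentRule:
    """derived species <- expression over other species.

    The expression is a sympy-parseable string; ``max(a, b)`` is allowed.
    """

    target: str
    expression: str

    def __post_init__(self):
        # canonicalise so equal expressions always serialise identically
        self.expression = sp.sstr(self.as_sympy())

    def as_sympy(self) -> sp.Expr:
        return sp.sympify(self.expression, locals={"max": sp.Max, "Max": sp.Max})


@dataclass
class Event:
    """At ``time``, add ``amount`` to species ``target`` (instantaneous)."""

    time: float
    target: str
    amount: float


@dataclass
class ReactionModel:
    name: str
    species: list[SpeciesDef]
    reactions: list[Reaction]
    rules: list[AssignmentRule] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    parameters: dict[str, Parameter] = field(default_factory=dict)
    #: species currently designated as the stimulus driving pathway input
    stimulus: str | None = None

    # -- lookups ---------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> SpeciesDef:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def dynamic_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if s.role == "dynamic"]

    def input_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if s.role == "input"]

    def derived_species(self) -> list[SpeciesDef]:
        return [s for s in self.species if s.role == "derived"]

    def parameter_ids(self) -> list[str]:
        return list(self.parameters)

    def parameter_values(self) -> dict[str, float]:
        return {p.id: p.value for p in self.parameters.values()}

    def copy(self) -> "ReactionModel":
        return copy.deepcopy(self)

    def with_parameters(self, values: dict[str, float]) -> "ReactionModel":
        m = self.copy()
        for pid, v in values.items():
            if pid not in m.parameters:
                raise KeyError(f"unknown parameter {pid!r}")
            m.parameters[pid] = replace(m.parameters[pid], value=float(v))
        return m


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: ReactionModel) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the model is well formed.  Violations are data,
    not exceptions, so callers can aggregate them across an ensemble.
    """
    v: list[str] = []
    ids = model.species_ids()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        v.append(f"duplicate species ids: {dupes}")
    known = set(ids)

    for s in model.species:
        if s.role not in ROLES:
            v.append(f"species {s.id}: unknown role {s.role!r}")
        if s.initial_value < 0:
            v.append(f"species {s.id}: negative initial value {s.initial_value}")

    rule_targets = {r.target for r in model.rules}
    for s in model.derived_species():
        if s.id not in rule_targets:
            v.append(f"derived species {s.id} has no assignment rule")
    for rule in model.rules:
        if rule.target not in known:
            v.append(f"assignment rule targets unknown species {rule.target}")
        elif model.get_species(rule.target).role != "derived":
            v.append(f"assignment rule target {rule.target} is not a derived species")
        for sym in rule.as_sympy().free_symbols:
            if str(sym) not in known:
                v.append(f"rule for {rule.target} references unknown symbol {sym}")

    rids = [r.id for r in model.reactions]
    if len(rids) != len(set(rids)):
        v.append("duplicate reaction ids")

    seen_params: dict[str, str] = {}
    for rxn in model.reactions:
        for sid in rxn.substrates + rxn.products:
            if sid not in known:
                v.append(f"reaction {rxn.id}: references non-existent species {sid}")
            elif model.get_species(sid).role != "dynamic":
                v.append(f"reaction {rxn.id}: {sid} is not a dynamic species")
        for sid, mrole in rxn.law.modifiers:
            if sid not in known:
                v.append(f"reaction {rxn.id}: modifier references non-existent species {sid}")
            if mrole not in ("catalyst", "inhibitor"):
                v.append(f"reaction {rxn.id}: unknown modifier role {mrole!r}")
        tmpl = rxn.law.template
        if tmpl not in KINETIC_TEMPLATES:
            v.append(f"reaction {rxn.id}: unknown kinetic template {tmpl!r}")
        else:
            want = KINETIC_TEMPLATES[tmpl]
            if len(rxn.law.parameter_ids) != want:
                v.append(
                    f"reaction {rxn.id}: template {tmpl} needs {want} parameters, "
                    f"got {len(rxn.law.parameter_ids)}"
                )
            if tmpl in ("michaelis_menten", "regulated_efflux") and len(rxn.substrates) != 1:
                v.append(f"reaction {rxn.id}: template {tmpl} needs exactly one substrate")
            if tmpl == "regulated_efflux" and rxn.law.inhibitor is None:
                v.append(f"reaction {rxn.id}: regulated_efflux needs an inhibitor modifier")
        for pid in rxn.law.parameter_ids:
            if pid not in model.parameters:
                v.append(f"reaction {rxn.id}: unknown parameter {pid}")
            elif pid in seen_params and seen_params[pid] != rxn.id:
                v.append(
                    f"parameter {pid} referenced by both {seen_params[pid]} and {rxn.id}"
                )
            else:
                seen_params[pid] = rxn.id

    for pid, par in model.parameters.items():
        if pid not in seen_params:
            v.append(f"parameter {pid} not referenced by any kinetic law")
        if not (par.lower > 0):
            v.append(f"parameter {pid}: lower bound must be strictly positive")
        if par.upper <= par.lower:
            v.append(f"parameter {pid}: empty bound interval [{par.lower}, {par.upper}]")
        if not (par.value > 0):
            v.append(f"parameter {pid}: value must be strictly positive")

    for ev in model.events:
        if ev.target not in known:
            v.append(f"event at t={ev.time}: unknown target species {ev.target}")
    if model.stimulus is not None and model.stimulus not in known:
        v.append(f"stimulus species {model.stimulus} does not exist")
    return v


# ---------------------------------------------------------------------------
# symbolic rates and the compiled right-hand side
# ---------------------------------------------------------------------------

def rate_expression(rxn: Reaction) -> sp.Expr:
    """Symbolic rate of one reaction in terms of species and parameter symbols."""
    law = rxn.law
    p = [sp.Symbol(pid, positive=True) for pid in law.parameter_ids]
    sub = [sp.Symbol(s) for s in rxn.substrates]
    cat = sp.Symbol(law.catalyst) if law.catalyst else None
    if law.template == "mass_action":
        expr = p[0]
        for s in sub:
            expr *= s
        if cat is not None:
            expr *= cat
        return expr
    if law.template == "michaelis_menten":
        (s,) = sub
        expr = p[0] * s / (p[1] + s)
        if cat is not None:
            expr *= cat
        return expr
    if law.template == "zero_order":
        return p[0]
    if law.template == "regulated_efflux":
        (s,) = sub
        inh = sp.Symbol(law.inhibitor)
        return p[0] * s / (p[1] + s) * p[2] / (p[2] + inh)
    raise ValueError(f"unknown kinetic template {law.template!r}")


def _derived_substitutions(model: ReactionModel) -> dict[sp.Symbol, sp.Expr]:
    """Substitutions eliminating derived species, resolved transitively."""
    subs = {sp.Symbol(r.target): r.as_sympy() for r in model.rules}
    # resolve rules referencing other derived species (fixpoint; rules are acyclic)
    for _ in range(len(subs)):
        subs = {k: e.subs(subs) for k, e in subs.items()}
    return subs


def symbolic_odes(model: ReactionModel) -> dict[str, sp.Expr]:
    """Map dynamic species id -> symbolic time derivative (derived species
    eliminated)."""
    subs = _derived_substitutions(model)
    odes: dict[str, sp.Expr] = {s.id: sp.Integer(0) for s in model.dynamic_species()}
    for rxn in model.reactions:
        rate = rate_expression(rxn).subs(subs)
        for sid in rxn.substrates:
            odes[sid] = odes[sid] - rate
        for sid in rxn.products:
            odes[sid] = odes[sid] + rate
    return odes


def build_rhs(model: ReactionModel):
    """Compile the model to ``f(t, y, pvec) -> dy`` for the ODE integrator.

    The state vector covers dynamic species followed by input species (inputs
    have zero derivative between events; events are applied by the simulator
    as integration restarts).  Returns ``(f, state_ids, param_ids)``.
    Raises ``ValueError`` for an unknown kinetic template.
    """
    problems = validate_model(model)
    if problems:
        raise ValueError("model does not validate: " + "; ".join(problems))
    odes = symbolic_odes(model)
    state_ids = [s.id for s in model.dynamic_species()] + [s.id for s in model.input_species()]
    param_ids = model.parameter_ids()
    y_syms = [sp.Symbol(s) for s in state_ids]
    p_syms = [sp.Symbol(p, positive=True) for p in param_ids]
    exprs = [odes[s] for s in state_ids if s in odes] + [
        sp.Integer(0) for s in model.input_species()
    ]
    f_scalar = sp.lambdify(y_syms + p_syms, exprs, modules=[{"Max": max, "Min": min}, "math"])

    def rhs(t, y, pvec):
        return f_scalar(*y, *pvec)

    return rhs, state_ids, param_ids


# ---------------------------------------------------------------------------
# stoichiometric analysis
# ---------------------------------------------------------------------------

def stoichiometry_matrix(model: ReactionModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Stoichiometry matrix N (dynamic species x reactions), with labels."""
    sids = [s.id for s in model.dynamic_species()]
    idx = {s: i for i, s in enumerate(sids)}
    rids = [r.id for r in model.reactions]
    N = np.zeros((len(sids), len(rids)))
    for j, rxn in enumerate(model.reactions):
        for s in rxn.substrates:
            N[idx[s], j] -= 1.0
        for s in rxn.products:
            N[idx[s], j] += 1.0
    return N, sids, rids


def conserved_moieties(model: ReactionModel) -> list[tuple[frozenset[str], float]]:
    """Conserved species pools, from the left null space of the stoichiometry
    matrix (exact rational arithmetic).

    Returns ``(species set, conserved total)`` pairs; the total is evaluated at
    the initial state.  Basis vectors are normalised to integer coefficients
    with positive leading entry; only non-negative vectors (true pools) are
    reported.
    """
    N, sids, _ = stoichiometry_matrix(model)
    if N.size == 0:
        return []
    M = sp.Matrix(N.astype(int)).T  # rows = reactions
    out = []
    for vec in M.nullspace():
        v = sp.Matrix(vec)
        denoms = [sp.fraction(sp.nsimplify(x))[1] for x in v]
        v = v * sp.lcm([sp.Integer(d) for d in denoms])
        nz = [x for x in v if x != 0]
        if nz and nz[0] < 0:
            v = -v
        g = sp.gcd([sp.Integer(x) for x in v if x != 0])
        v = v / g
        if any(x < 0 for x in v):
            continue
        members = frozenset(sids[i] for i in range(len(sids)) if v[i] != 0)
        total = float(
            sum(int(v[i]) * model.get_species(sids[i]).initial_value for i in range(len(sids)))
        )
        out.append((members, total))
    out.sort(key=lambda m: sorted(m[0]))
    return out
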