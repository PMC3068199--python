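"""SBML Level 3 Version 1 import/export for the supported model subset.

The subset covers: a single compartment, species, global parameters,
irreversible unit-stoichiometry reactions with templated kinetic laws,
assignment rules for derived species, and timed-addition events.  The
kinetic template, parameter order, modifier roles, fitting bounds and the
stimulus designation have no SBML-core representation, so they travel in a
custom annotation namespace; the rate law itself is written as standard
MathML so any SBML-compliant simulator can run the exported file.

Import of documents using constructs outside the subset (rate rules,
algebraic rules, function definitions, multiple compartments, reversible
reactions, non-unit stoichiometry) fails with an error naming them.
"""

from __future__ import annotations

import sympy as sp

import libsbml

from .model import (
    AssignmentRule,
    Event,
    KineticLaw,
    Parameter,
    Reaction,
    ReactionModel,
    SpeciesDef,
    rate_expression,
)

__all__ = ["export_sbml", "import_sbml"]

_NS = "http://ensemblemage.org/ns"


class SBMLImportError(ValueError):
    """Raised when a document uses constructs outside the supported subset."""


# ---------------------------------------------------------------------------
# sympy <-> SBML math
# ---------------------------------------------------------------------------

def _sympy_to_l3(expr: sp.Expr) -> str:
    """Render a sympy expression as an SBML L3 formula string.

    ``Max(a, b)`` becomes ``piecewise(a, a >= b, b)`` because min/max are not
    core L3V1 functions.
    """
    if isinstance(expr, sp.Max):
        if len(expr.args) != 2:
            raise ValueError("only binary Max supported")
        a, b = (_sympy_to_l3(x) for x in expr.args)
        return f"piecewise({a}, ({a}) >= ({b}), {b})"
    if isinstance(expr, (sp.Add, sp.Mul, sp.Pow)):
        # recurse so nested Max gets translated
        op = {"Add": " + ", "Mul": " * "}.get(type(expr).__name__)
        if op is not None:
            return op.join(f"({_sympy_to_l3(a)})" for a in expr.args)
        base, ex = expr.args
        return f"({_sympy_to_l3(base)})^({_sympy_to_l3(ex)})"
    return sp.sstr(expr)


def _pw(*args):
    pairs = [(args[i], args[i + 1]) for i in range(0, len(args) - 1, 2)]
    if len(args) % 2 == 1:
        pairs.append((args[-1], sp.true))
    return sp.Piecewise(*pairs)


_L3_LOCALS = {
    "piecewise": _pw,
    "geq": sp.Ge,
    "leq": sp.Le,
    "gt": sp.Gt,
    "lt": sp.Lt,
    "pow": sp.Pow,
    "max": sp.Max,
    "min": sp.Min,
}


def _l3_to_sympy(formula: str) -> sp.Expr:
    expr = sp.sympify(formula.replace("^", "**"), locals=_L3_LOCALS)
    return _piecewise_to_max(expr)


def _piecewise_to_max(expr: sp.Expr) -> sp.Expr:
    # recognise {v1 if v1 >= v2 else v2} as Max(v1, v2), robust to sympy's
    # canonicalisation of the relational (side swaps / sign flips)
    if isinstance(expr, sp.Piecewise) and len(expr.args) == 2:
        (v1, c1), (v2, c2) = expr.args
        if c2 in (sp.true, True) and isinstance(c1, (sp.Ge, sp.Gt, sp.Le, sp.Lt)):
            if isinstance(c1, (sp.Ge, sp.Gt)):
                diff = c1.lhs - c1.rhs
            else:
                diff = c1.rhs - c1.lhs
            if sp.simplify(diff - (v1 - v2)) == 0:
                return sp.Max(v1, v2)
    if expr.args:
        return expr.func(*[_piecewise_to_max(a) for a in expr.args])
    return expr


def _parse_l3(formula_node) -> sp.Expr:
    return _l3_to_sympy(libsbml.formulaToL3String(formula_node))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _set_math(element, formula: str) -> None:
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise ValueError(f"cannot parse formula: {formula}")
    element.setMath(ast)


def export_sbml(model: ReactionModel) -> str:
    """Serialise the model to an SBML L3V1 document string."""
    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId(model.name.replace("-", "_"))
    m.setName(model.name)
    if model.stimulus is not None:
        m.setAnnotation(
            f'<em:info xmlns:em="{_NS}" stimulus="{model.stimulus}"/>'
        )

    comp = m.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    for s in model.species:
        sb = m.createSpecies()
        sb.setId(s.id)
        sb.setCompartment("cell")
        sb.setInitialConcentration(float(s.initial_value))
        sb.setBoundaryCondition(s.role in ("input", "derived"))
        sb.setConstant(False)
        sb.setHasOnlySubstanceUnits(False)
        sb.setAnnotation(f'<em:species xmlns:em="{_NS}" role="{s.role}"/>')

    for p in model.parameters.values():
        pb = m.createParameter()
        pb.setId(p.id)
        pb.setValue(float(p.value))
        pb.setConstant(True)
        pb.setAnnotation(
            f'<em:bounds xmlns:em="{_NS}" lower="{p.lower!r}" upper="{p.upper!r}"/>'
        )

    for rule in model.rules:
        rb = m.createAssignmentRule()
        rb.setVariable(rule.target)
        _set_math(rb, _sympy_to_l3(rule.as_sympy()))

    for rxn in model.reactions:
        rb = m.createReaction()
        rb.setId(rxn.id)
        rb.setReversible(False)
        rb.setFast(False)
        mods = "".join(
            f'<em:modifier species="{sid}" role="{role}"/>'
            for sid, role in rxn.law.modifiers
        )
        rb.setAnnotation(
            f'<em:kinetics xmlns:em="{_NS}" template="{rxn.law.template}" '
            f'parameters="{",".join(rxn.law.parameter_ids)}">{mods}</em:kinetics>'
        )
        for sid in rxn.substrates:
            ref = rb.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for sid in rxn.products:
            ref = rb.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for sid, _role in rxn.law.modifiers:
            mref = rb.createModifier()
            mref.setSpecies(sid)
        kl = rb.createKineticLaw()
        _set_math(kl, _sympy_to_l3(rate_expression(rxn)))

    for ev in model.events:
        eb = m.createEvent()
        eb.setUseValuesFromTriggerTime(True)
        tr = eb.createTrigger()
        tr.setInitialValue(True)
        tr.setPersistent(True)
        _set_math(tr, f"time >= {ev.time!r}")
        ea = eb.createEventAssignment()
        ea.setVariable(ev.target)
        _set_math(ea, f"{ev.target} + {ev.amount!r}")

    return libsbml.writeSBMLToString(doc)


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _annotation_attr(element, tag: str, attr: str) -> str | None:
    node = element.getAnnotation()
    if node is None:
        return None
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getName() == tag:
            val = child.getAttrValue(attr)
            if val:
                return val
    return None


def _kinetics_annotation(rxn) -> tuple[str, list[str], list[tuple[str, str]]] | None:
    node = rxn.getAnnotation()
    if node is None:
        return None
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getName() != "kinetics":
            continue
        template = child.getAttrValue("template")
        params = [p for p in child.getAttrValue("parameters").split(",") if p]
        mods = []
        for j in range(child.getNumChildren()):
            mc = child.getChild(j)
            if mc.getName() == "modifier":
                mods.append((mc.getAttrValue("species"), mc.getAttrValue("role")))
        return template, params, mods
    return None


def import_sbml(document: str) -> ReactionModel:
    """Parse an SBML document string into a :class:`ReactionModel`.

    Raises :class:`SBMLImportError` naming any unsupported construct.
    """
    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLImportError("SBML parse errors: " + " | ".join(msgs))
    m = doc.getModel()
    if m is None:
        raise SBMLImportError("document contains no model")

    unsupported: list[str] = []
    if m.getNumFunctionDefinitions():
        unsupported.append("functionDefinition")
    if m.getNumCompartments() > 1:
        unsupported.append("multiple compartments")
    for i in range(m.getNumRules()):
        r = m.getRule(i)
        if r.isRate():
            unsupported.append(f"rateRule ({r.getVariable()})")
        elif r.isAlgebraic():
            unsupported.append("algebraicRule")
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        if r.getReversible():
            unsupported.append(f"reversible reaction ({r.getId()})")
        for ref in list(r.getListOfReactants()) + list(r.getListOfProducts()):
            if ref.getStoichiometry() != 1.0:
                unsupported.append(f"non-unit stoichiometry ({r.getId()})")
    if unsupported:
        raise SBMLImportError("unsupported SBML constructs: " + ", ".join(unsupported))

    rule_targets = {m.getRule(i).getVariable() for i in range(m.getNumRules())}
    species = []
    for i in range(m.getNumSpecies()):
        sb = m.getSpecies(i)
        role = _annotation_attr(sb, "species", "role")
        if role is None:
            if sb.getId() in rule_targets:
                role = "derived"
            elif sb.getBoundaryCondition():
                role = "input"
            else:
                role = "dynamic"
        init = sb.getInitialConcentration()
        if init != init:  # NaN -> fall back to amount
            init = sb.getInitialAmount()
        species.append(SpeciesDef(id=sb.getId(), role=role, initial_value=float(init)))

    params: dict[str, Parameter] = {}
    for i in range(m.getNumParameters()):
        pb = m.getParameter(i)
        lower = _annotation_attr(pb, "bounds", "lower")
        upper = _annotation_attr(pb, "bounds", "upper")
        params[pb.getId()] = Parameter(
            id=pb.getId(),
            value=float(pb.getValue()),
            lower=float(lower) if lower else 1e-6,
            upper=float(upper) if upper else 1e3,
        )

    rules = []
    for i in range(m.getNumRules()):
        r = m.getRule(i)
        expr = _parse_l3(r.getMath())
        rules.append(AssignmentRule(target=r.getVariable(), expression=sp.sstr(expr)))

    reactions = []
    for i in range(m.getNumReactions()):
        rb = m.getReaction(i)
        ann = _kinetics_annotation(rb)
        if ann is None:
            raise SBMLImportError(
                f"reaction {rb.getId()}: kinetic law is not in a supported template form"
            )
        template, pids, mods = ann
        reactions.append(
            Reaction(
                id=rb.getId(),
                substrates=[rb.getReactant(j).getSpecies() for j in range(rb.getNumReactants())],
                products=[rb.getProduct(j).getSpecies() for j in range(rb.getNumProducts())],
                law=KineticLaw(template=template, parameter_ids=pids, modifiers=mods),
            )
        )

    events = []
    t = sp.Symbol("time")
    for i in range(m.getNumEvents()):
        eb = m.getEvent(i)
        trig = _parse_l3(eb.getTrigger().getMath())
        if not (isinstance(trig, sp.Ge) and trig.lhs == t and trig.rhs.is_number):
            raise SBMLImportError(f"event trigger not of form 'time >= c': {trig}")
        when = float(trig.rhs)
        for j in range(eb.getNumEventAssignments()):
            ea = eb.getEventAssignment(j)
            target = ea.getVariable()
            delta = sp.expand(_parse_l3(ea.getMath()) - sp.Symbol(target))
            if not delta.is_number:
                raise SBMLImportError(
                    f"event assignment not of form '{target} + c': {ea.getVariable()}"
                )
            events.append(Event(time=when, target=target, amount=float(delta)))

    return ReactionModel(
        name=m.getName() or m.getId(),
        species=species,
        reactions=reactions,
        rules=rules,
        events=events,
        parameters=params,
        stimulus=_annotation_attr(m, "info", "stimulus"),
    )
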