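"""Minimal SBML Level 3 import/export for model structure.

Writes species, global parameters, and reactions (with content-MathML
kinetic laws) and reads them back.  Package-specific structure that SBML
core does not model (reaction kinds, conserved moieties, observable
definitions, canonical parameter order) travels in a namespaced annotation
so that export -> import round-trips exactly.  Reading foreign SBML files is
supported for the constructs this module emits; anything else (events,
rules, function definitions, unit definitions) is collected into a report of
unmapped constructs rather than silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import sympy as sp
from lxml import etree

from .network import Reaction, SignalingModel, build_signaling_model

__all__ = ["write_sbml", "read_sbml", "structure_diff", "SBMLFormatError",
           "StructureDiff"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:eposignal:model-structure"


class SBMLFormatError(ValueError):
    """Unparseable or structurally unusable SBML input."""


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# -- MathML (content) emission and parsing ----------------------------------

def _expr_to_mathml(expr: sp.Expr) -> etree._Element:
    def build(e):
        if e.is_Symbol:
            el = etree.Element(_q("ci", MATHML_NS))
            el.text = str(e)
            return el
        if e.is_Number:
            el = etree.Element(_q("cn", MATHML_NS))
            el.text = repr(float(e))
            return el
        if isinstance(e, sp.Add):
            return apply_op("plus", e.args)
        if isinstance(e, sp.Mul):
            return apply_op("times", e.args)
        if isinstance(e, sp.Pow):
            return apply_op("power", e.args)
        if isinstance(e, sp.Max):
            return apply_op("max", e.args)
        raise SBMLFormatError(f"cannot serialize expression node {e!r}")

    def apply_op(op, args):
        el = etree.Element(_q("apply", MATHML_NS))
        el.append(etree.Element(_q(op, MATHML_NS)))
        for a in args:
            el.append(build(a))
        return el

    math = etree.Element(_q("math", MATHML_NS))
    math.append(build(sp.sympify(expr)))
    return math


_OPS = {"plus": lambda *a: sp.Add(*a),
        "times": lambda *a: sp.Mul(*a),
        "minus": lambda *a: a[0] - a[1] if len(a) == 2 else -a[0],
        "divide": lambda a, b: a / b,
        "power": lambda a, b: sp.Pow(a, b),
        "max": lambda *a: sp.Max(*a)}


def _mathml_to_expr(math_el: etree._Element) -> sp.Expr:
    def parse(el):
        tag = etree.QName(el).localname
        if tag == "ci":
            return sp.Symbol(el.text.strip())
        if tag == "cn":
            v = float(el.text.strip())
            return sp.Integer(v) if v == int(v) else sp.Float(v)
        if tag == "apply":
            children = [c for c in el if isinstance(c.tag, str)]
            op = etree.QName(children[0]).localname
            if op not in _OPS:
                raise SBMLFormatError(f"unsupported MathML operator <{op}>")
            return _OPS[op](*[parse(c) for c in children[1:]])
        raise SBMLFormatError(f"unsupported MathML element <{tag}>")

    children = [c for c in math_el if isinstance(c.tag, str)]
    if len(children) != 1:
        raise SBMLFormatError("math element must have exactly one child")
    return parse(children[0])


# -- export ------------------------------------------------------------------

def write_sbml(model: SignalingModel, path: str) -> None:
    """Serialize a model to SBML L3V2 with a structure annotation."""
    nsmap = {None: SBML_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mdl = etree.SubElement(root, _q("model"))
    mdl.set("id", model.name)

    annot = etree.SubElement(mdl, _q("annotation"))
    extra = etree.SubElement(annot, f"{{{ANNOT_NS}}}structure",
                             nsmap={"eps": ANNOT_NS})
    extra.text = json.dumps(dict(
        kinds={r.name: r.kind for r in model.reactions},
        modifiers={r.name: list(r.modifiers) for r in model.reactions},
        moieties=model.moieties,
        observables=model.observables,
        parameter_order=model.parameters,
    ))

    comps = etree.SubElement(mdl, _q("listOfCompartments"))
    comp = etree.SubElement(comps, _q("compartment"))
    comp.set("id", "cytoplasm")
    comp.set("constant", "true")

    species_el = etree.SubElement(mdl, _q("listOfSpecies"))
    for s in model.species:
        el = etree.SubElement(species_el, _q("species"))
        el.set("id", s)
        el.set("compartment", "cytoplasm")
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition", "false")
        el.set("constant", "false")

    params_el = etree.SubElement(mdl, _q("listOfParameters"))
    for p in model.parameters:
        el = etree.SubElement(params_el, _q("parameter"))
        el.set("id", p)
        el.set("value", repr(model.theta_default[p]))
        el.set("constant", "true")

    rxns_el = etree.SubElement(mdl, _q("listOfReactions"))
    for r in model.reactions:
        el = etree.SubElement(rxns_el, _q("reaction"))
        el.set("id", r.name)
        el.set("reversible", "false")
        if r.reactants:
            lst = etree.SubElement(el, _q("listOfReactants"))
            for s, nu in r.reactants.items():
                ref = etree.SubElement(lst, _q("speciesReference"))
                ref.set("species", s)
                ref.set("stoichiometry", str(nu))
                ref.set("constant", "true")
        if r.products:
            lst = etree.SubElement(el, _q("listOfProducts"))
            for s, nu in r.products.items():
                ref = etree.SubElement(lst, _q("speciesReference"))
                ref.set("species", s)
                ref.set("stoichiometry", str(nu))
                ref.set("constant", "true")
        if r.modifiers:
            lst = etree.SubElement(el, _q("listOfModifiers"))
            for s in r.modifiers:
                ref = etree.SubElement(lst, _q("modifierSpeciesReference"))
                ref.set("species", s)
        klaw = etree.SubElement(el, _q("kineticLaw"))
        klaw.append(_expr_to_mathml(sp.sympify(
            r.rate, locals={"Max": sp.Max})))

    etree.ElementTree(root).write(path, pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


# -- import ------------------------------------------------------------------

_UNSUPPORTED = ("listOfEvents", "listOfRules", "listOfFunctionDefinitions",
                "listOfConstraints", "listOfInitialAssignments")


def read_sbml(path: str, warn=None) -> SignalingModel:
    """Parse SBML into a :class:`SignalingModel`.

    ``warn`` is an optional callable receiving one message per unmapped
    construct (defaults to collecting into the returned model's
    ``import_warnings`` attribute).
    """
    try:
        tree = etree.parse(path)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLFormatError(f"cannot parse {path!r}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise SBMLFormatError(f"{path!r}: root element is not <sbml>")
    mdl = root.find(_q("model"))
    if mdl is None:
        # tolerate level-2 namespaces by local-name search
        cands = [c for c in root if isinstance(c.tag, str)
                 and etree.QName(c).localname == "model"]
        if not cands:
            raise SBMLFormatError(f"{path!r}: no <model> element")
        mdl = cands[0]
    ns = etree.QName(mdl).namespace or SBML_NS

    warnings: list[str] = []
    emit = warn if warn is not None else warnings.append
    for child in mdl:
        if isinstance(child.tag, str) and \
                etree.QName(child).localname in _UNSUPPORTED:
            emit(f"unsupported construct <{etree.QName(child).localname}> "
                 f"ignored (path: model/{etree.QName(child).localname})")

    def find(tag):
        el = mdl.find(f"{{{ns}}}{tag}")
        return el if el is not None else []

    extra = {}
    annot = mdl.find(f"{{{ns}}}annotation")
    if annot is not None:
        st = annot.find(f"{{{ANNOT_NS}}}structure")
        if st is not None and st.text:
            extra = json.loads(st.text)

    species = [el.get("id") for el in find("listOfSpecies")]
    parameters, theta = [], {}
    for el in find("listOfParameters"):
        parameters.append(el.get("id"))
        theta[el.get("id")] = float(el.get("value", "nan"))
    if extra.get("parameter_order"):
        parameters = extra["parameter_order"]

    reactions = []
    for el in find("listOfReactions"):
        rid = el.get("id")
        reactants, products, modifiers = {}, {}, []
        for lst, target in ((el.find(f"{{{ns}}}listOfReactants"), reactants),
                            (el.find(f"{{{ns}}}listOfProducts"), products)):
            if lst is not None:
                for ref in lst:
                    if isinstance(ref.tag, str):
                        target[ref.get("species")] = int(
                            float(ref.get("stoichiometry", "1")))
        lst = el.find(f"{{{ns}}}listOfModifiers")
        if lst is not None:
            modifiers = [ref.get("species") for ref in lst
                         if isinstance(ref.tag, str)]
        klaw = el.find(f"{{{ns}}}kineticLaw")
        if klaw is None:
            emit(f"reaction {rid!r} has no kineticLaw; rate set to 0")
            rate = "0"
        else:
            math = klaw.find(_q("math", MATHML_NS))
            if math is None:
                emit(f"reaction {rid!r}: kineticLaw without MathML")
                rate = "0"
            else:
                try:
                    rate = str(_mathml_to_expr(math))
                except SBMLFormatError as exc:
                    emit(f"reaction {rid!r}: {exc}; rate set to 0")
                    rate = "0"
        kind = extra.get("kinds", {}).get(rid, "mass_action")
        mods = tuple(extra.get("modifiers", {}).get(rid, modifiers))
        reactions.append(Reaction(rid, reactants, products, kind, rate, mods))

    model = build_signaling_model(dict(
        name=mdl.get("id", "imported"),
        species=species,
        reactions=reactions,
        parameters=parameters,
        moieties=extra.get("moieties", {}),
        observables=extra.get("observables", {}),
        theta_default=theta,
    ))
    model.import_warnings = warnings
    return model


# -- structure diff ----------------------------------------------------------

@dataclass
class StructureDiff:
    """Differences between two model structures; listed, not judged."""

    species_only_a: list[str] = field(default_factory=list)
    species_only_b: list[str] = field(default_factory=list)
    parameters_only_a: list[str] = field(default_factory=list)
    parameters_only_b: list[str] = field(default_factory=list)
    reactions_only_a: list[str] = field(default_factory=list)
    reactions_only_b: list[str] = field(default_factory=list)
    changed_reactions: list[str] = field(default_factory=list)

    @property
    def identical(self) -> bool:
        return not any(getattr(self, f) for f in (
            "species_only_a", "species_only_b", "parameters_only_a",
            "parameters_only_b", "reactions_only_a", "reactions_only_b",
            "changed_reactions"))

    def report(self) -> str:
        if self.identical:
            return "structures identical"
        lines = []
        for f in ("species_only_a", "species_only_b", "parameters_only_a",
                  "parameters_only_b", "reactions_only_a", "reactions_only_b",
                  "changed_reactions"):
            vals = getattr(self, f)
            if vals:
                lines.append(f"{f}: {', '.join(vals)}")
        return "\n".join(lines)


def structure_diff(a: SignalingModel, b: SignalingModel) -> StructureDiff:
    """Graph-level comparison of two models (species, parameters, reactions,
    stoichiometry, and symbolic rate laws)."""
    diff = StructureDiff(
        species_only_a=sorted(set(a.species) - set(b.species)),
        species_only_b=sorted(set(b.species) - set(a.species)),
        parameters_only_a=sorted(set(a.parameters) - set(b.parameters)),
        parameters_only_b=sorted(set(b.parameters) - set(a.parameters)),
    )
    ra = {r.name: r for r in a.reactions}
    rb = {r.name: r for r in b.reactions}
    diff.reactions_only_a = sorted(set(ra) - set(rb))
    diff.reactions_only_b = sorted(set(rb) - set(ra))
    local = {"Max": sp.Max}
    for name in sorted(set(ra) & set(rb)):
        x, y = ra[name], rb[name]
        same_stoich = (x.reactants == y.reactants and x.products == y.products)
        same_rate = sp.simplify(
            sp.sympify(x.rate, locals=local)
            - sp.sympify(y.rate, locals=local)) == 0
        if not (same_stoich and same_rate):
            diff.changed_reactions.append(name)
    return diff
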