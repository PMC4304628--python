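"""Minimal SBML reader/writer for the kinetics subset this package uses.

Supports SBML Level 2 (v4-style) and Level 3 Version 1 documents containing
species, global/local parameters, and irreversible reactions whose kinetic
laws are sums of mass-action / Michaelis-Menten-style terms:

    k * [S1] * ... * [Sa]/(Km + [Sa]) * ...

Kinetic-law MathML is parsed into sympy and decomposed back into the
structured :class:`~trialvoi.kinetics.RateTerm` form; anything outside the
subset (events, rules, assignments, non-matching rate expressions) raises
:class:`UnsupportedConstructError` naming the offending reaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import sympy
from lxml import etree

from .kinetics import (KineticsError, RateParameterSet, RateTerm, Reaction,
                       ReactionNetwork, Species)

__all__ = ["SBMLParseError", "UnsupportedConstructError", "EmptyNetworkError",
           "ImportedModel", "import_sbml_subset", "export_sbml"]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
SBML_L2_NS_PREFIX = "http://www.sbml.org/sbml/level2"


class SBMLParseError(KineticsError):
    """Malformed XML or structurally invalid SBML."""


class UnsupportedConstructError(SBMLParseError):
    """SBML construct outside the supported subset; names the reaction."""

    def __init__(self, message: str, reaction_id: str | None = None):
        super().__init__(message)
        self.reaction_id = reaction_id


class EmptyNetworkError(SBMLParseError):
    """The document defines no reactions."""


@dataclass
class ImportedModel:
    """Result of an SBML import: the network plus the file's constants."""

    network: ReactionNetwork
    parameters: RateParameterSet


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _math_symbol(parent, name: str):
    ci = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
    ci.text = f" {name} "


def _term_math(parent, term: RateTerm) -> None:
    """Emit <apply><times/> k S ... S/(Km+S) ...</apply> (or bare ci)."""
    factors = 1 + len(term.linear) + len(term.saturating)
    if factors == 1:
        _math_symbol(parent, term.constant)
        return
    apply_ = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
    _math_symbol(apply_, term.constant)
    for s in term.linear:
        _math_symbol(apply_, s)
    for s, km in term.saturating:
        div = etree.SubElement(apply_, f"{{{MATHML_NS}}}apply")
        etree.SubElement(div, f"{{{MATHML_NS}}}divide")
        _math_symbol(div, s)
        add = etree.SubElement(div, f"{{{MATHML_NS}}}apply")
        etree.SubElement(add, f"{{{MATHML_NS}}}plus")
        _math_symbol(add, km)
        _math_symbol(add, s)


def export_sbml(network: ReactionNetwork, params: Mapping[str, float], path) -> None:
    """Write the network and its rate constants as SBML Level 3 Version 1."""
    nsmap = {None: SBML_L3_NS}
    root = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap,
                         attrib={"level": "3", "version": "1"})
    model = etree.SubElement(root, f"{{{SBML_L3_NS}}}model",
                             attrib={"id": "selenium_metabolism"})
    comps = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_L3_NS}}}compartment",
                     attrib={"id": "cell", "size": "1", "constant": "true",
                             "spatialDimensions": "3"})
    sps = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfSpecies")
    for s in network.species:
        etree.SubElement(sps, f"{{{SBML_L3_NS}}}species", attrib={
            "id": s.name, "compartment": "cell",
            "initialConcentration": repr(float(s.initial_concentration)),
            "boundaryCondition": "true" if s.clamped else "false",
            "constant": "false", "hasOnlySubstanceUnits": "false"})
    pars = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfParameters")
    for name in network.parameter_names:
        etree.SubElement(pars, f"{{{SBML_L3_NS}}}parameter", attrib={
            "id": name, "value": repr(float(params[name])), "constant": "true"})
    rxns = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfReactions")
    for r in network.reactions:
        rx = etree.SubElement(rxns, f"{{{SBML_L3_NS}}}reaction",
                              attrib={"id": r.id, "reversible": "false",
                                      "fast": "false"})
        if r.reactants:
            lst = etree.SubElement(rx, f"{{{SBML_L3_NS}}}listOfReactants")
            for name, c in r.reactants:
                etree.SubElement(lst, f"{{{SBML_L3_NS}}}speciesReference",
                                 attrib={"species": name, "stoichiometry": str(c),
                                         "constant": "true"})
        if r.products:
            lst = etree.SubElement(rx, f"{{{SBML_L3_NS}}}listOfProducts")
            for name, c in r.products:
                etree.SubElement(lst, f"{{{SBML_L3_NS}}}speciesReference",
                                 attrib={"species": name, "stoichiometry": str(c),
                                         "constant": "true"})
        if r.modifiers:
            lst = etree.SubElement(rx, f"{{{SBML_L3_NS}}}listOfModifiers")
            for name in r.modifiers:
                etree.SubElement(lst, f"{{{SBML_L3_NS}}}modifierSpeciesReference",
                                 attrib={"species": name})
        kl = etree.SubElement(rx, f"{{{SBML_L3_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        if len(r.terms) == 1:
            _term_math(math, r.terms[0])
        else:
            apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
            etree.SubElement(apply_, f"{{{MATHML_NS}}}plus")
            for t in r.terms:
                _term_math(apply_, t)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_sympy(node, symbols: Dict[str, sympy.Symbol], rxn_id: str):
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise UnsupportedConstructError(
                f"reaction {rxn_id!r}: kinetic law must be a single expression",
                rxn_id)
        return _mathml_to_sympy(children[0], symbols, rxn_id)
    if tag == "ci":
        name = (node.text or "").strip()
        if not name:
            raise UnsupportedConstructError(
                f"reaction {rxn_id!r}: empty <ci> in kinetic law", rxn_id)
        return symbols.setdefault(name, sympy.Symbol(name))
    if tag == "cn":
        try:
            return sympy.Rational(str((node.text or "").strip()))
        except Exception:
            try:
                return sympy.Float((node.text or "").strip())
            except Exception:
                raise UnsupportedConstructError(
                    f"reaction {rxn_id!r}: unparseable numeric literal", rxn_id)
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        if not children:
            raise UnsupportedConstructError(
                f"reaction {rxn_id!r}: empty <apply>", rxn_id)
        op = _local(children[0].tag)
        args = [_mathml_to_sympy(c, symbols, rxn_id) for c in children[1:]]
        if op == "plus":
            return sympy.Add(*args)
        if op == "times":
            return sympy.Mul(*args)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            if len(args) == 2:
                return args[0] - args[1]
        if op == "divide" and len(args) == 2:
            return args[0] / args[1]
        if op == "power" and len(args) == 2:
            return args[0] ** args[1]
        raise UnsupportedConstructError(
            f"reaction {rxn_id!r}: unsupported MathML operator <{op}>", rxn_id)
    raise UnsupportedConstructError(
        f"reaction {rxn_id!r}: unsupported MathML element <{tag}>", rxn_id)


def _decompose_rate_law(expr, species: set, parameters: set,
                        rxn_id: str) -> tuple[RateTerm, ...]:
    """Split a sympy rate expression into structured terms.

    Each additive term must be  k * prod(species) * prod(S/(Km+S)).
    """
    terms = []
    for addend in sympy.Add.make_args(sympy.expand(expr)):
        constant = None
        linear: list[str] = []
        denominators: list[tuple[str, str]] = []  # (species, km)
        factors = []
        for f in sympy.Mul.make_args(addend):
            if isinstance(f, sympy.Pow) and f.exp.is_Integer:
                n = int(f.exp)
                factors.extend([f.base] * n if n > 0 else [1 / f.base] * (-n))
            else:
                factors.append(f)
        for f in factors:
            if f is sympy.S.One or f == 1:
                continue
            if f.is_Number:
                raise UnsupportedConstructError(
                    f"reaction {rxn_id!r}: numeric coefficient {f} in kinetic "
                    "law (constants must be named parameters)", rxn_id)
            if isinstance(f, sympy.Symbol):
                name = f.name
                if name in species:
                    linear.append(name)
                elif name in parameters:
                    if constant is not None:
                        raise UnsupportedConstructError(
                            f"reaction {rxn_id!r}: term with more than one rate "
                            "constant", rxn_id)
                    constant = name
                else:
                    raise UnsupportedConstructError(
                        f"reaction {rxn_id!r}: unknown identifier {name!r} in "
                        "kinetic law", rxn_id)
                continue
            if isinstance(f, sympy.Pow) and f.exp == -1:
                base = sympy.expand(f.base)
                args = sympy.Add.make_args(base)
                syms = [a for a in args if isinstance(a, sympy.Symbol)]
                if (len(args) == 2 and len(syms) == 2
                        and {args[0], args[1]} == set(syms)):
                    names = {s.name for s in syms}
                    sp = names & species
                    km = names & parameters
                    if len(sp) == 1 and len(km) == 1:
                        denominators.append((next(iter(sp)), next(iter(km))))
                        continue
                raise UnsupportedConstructError(
                    f"reaction {rxn_id!r}: denominator {f.base} is not of the "
                    "form (Km + S)", rxn_id)
            raise UnsupportedConstructError(
                f"reaction {rxn_id!r}: unsupported factor {f} in kinetic law",
                rxn_id)
        if constant is None:
            raise UnsupportedConstructError(
                f"reaction {rxn_id!r}: term without a named rate constant",
                rxn_id)
        saturating = []
        for sp, km in denominators:
            if sp not in linear:
                raise UnsupportedConstructError(
                    f"reaction {rxn_id!r}: denominator (Km + {sp}) lacks a "
                    f"matching {sp} numerator factor", rxn_id)
            linear.remove(sp)
            saturating.append((sp, km))
        terms.append(RateTerm(constant=constant, linear=tuple(linear),
                              saturating=tuple(saturating)))
    return tuple(terms)


def _find(parent, name: str):
    for child in parent:
        if isinstance(child.tag, str) and _local(child.tag) == name:
            yield child


def _find_one(parent, name: str):
    for child in _find(parent, name):
        return child
    return None


def import_sbml_subset(path) -> ImportedModel:
    """Read a restricted-subset SBML file into a network plus constants.

    Raises :class:`SBMLParseError` on malformed XML,
    :class:`EmptyNetworkError` when no reactions are defined, and
    :class:`UnsupportedConstructError` (naming the reaction) for kinetic laws
    outside the mass-action/saturating subset.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLParseError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLParseError("root element is not <sbml>")
    ns = root.tag[1:].split("}", 1)[0] if root.tag.startswith("{") else ""
    if not (ns == SBML_L3_NS or ns.startswith(SBML_L2_NS_PREFIX)):
        raise SBMLParseError(f"unsupported SBML namespace {ns!r}")
    model = _find_one(root, "model")
    if model is None:
        raise SBMLParseError("no <model> element")
    for construct in ("listOfEvents", "listOfRules", "listOfConstraints",
                      "listOfInitialAssignments", "listOfFunctionDefinitions"):
        if _find_one(model, construct) is not None:
            raise UnsupportedConstructError(
                f"unsupported SBML construct <{construct}>")

    species = []
    sp_list = _find_one(model, "listOfSpecies")
    if sp_list is not None:
        for el in _find(sp_list, "species"):
            conc = el.get("initialConcentration")
            if conc is None:
                conc = el.get("initialAmount", "0")
            species.append(Species(
                name=el.get("id"),
                initial_concentration=float(conc),
                clamped=el.get("boundaryCondition", "false") == "true"))
    params: RateParameterSet = {}
    par_list = _find_one(model, "listOfParameters")
    if par_list is not None:
        for el in _find(par_list, "parameter"):
            if el.get("value") is None:
                raise SBMLParseError(
                    f"parameter {el.get('id')!r} has no value")
            params[el.get("id")] = float(el.get("value"))

    species_names = {s.name for s in species}
    reactions = []
    rxn_list = _find_one(model, "listOfReactions")
    rxn_elements = list(_find(rxn_list, "reaction")) if rxn_list is not None else []
    if not rxn_elements:
        raise EmptyNetworkError("SBML model defines no reactions")

    for el in rxn_elements:
        rid = el.get("id")
        if el.get("reversible", "false") == "true":
            raise UnsupportedConstructError(
                f"reaction {rid!r}: reversible reactions are not supported", rid)

        def refs(list_name):
            lst = _find_one(el, list_name)
            out = []
            if lst is not None:
                for ref in _find(lst, "speciesReference"):
                    out.append((ref.get("species"),
                                int(float(ref.get("stoichiometry", "1")))))
            return tuple(out)

        modifiers = []
        mod_list = _find_one(el, "listOfModifiers")
        if mod_list is not None:
            for ref in _find(mod_list, "modifierSpeciesReference"):
                modifiers.append(ref.get("species"))

        kl = _find_one(el, "kineticLaw")
        if kl is None:
            raise UnsupportedConstructError(
                f"reaction {rid!r}: missing kinetic law", rid)
        for loc_name in ("listOfLocalParameters", "listOfParameters"):
            loc = _find_one(kl, loc_name)
            if loc is not None:
                for p in _find(loc, "localParameter" if "Local" in loc_name
                               else "parameter"):
                    pid = p.get("id")
                    if pid in params:
                        raise UnsupportedConstructError(
                            f"reaction {rid!r}: local parameter {pid!r} shadows "
                            "a global parameter", rid)
                    params[pid] = float(p.get("value"))
        math = _find_one(kl, "math")
        if math is None:
            raise UnsupportedConstructError(
                f"reaction {rid!r}: kinetic law has no <math>", rid)
        expr = _mathml_to_sympy(math, {}, rid)
        terms = _decompose_rate_law(expr, species_names, set(params), rid)
        reactions.append(Reaction(id=rid, reactants=refs("listOfReactants"),
                                  products=refs("listOfProducts"),
                                  modifiers=tuple(modifiers), terms=terms))

    used = []
    for r in reactions:
        used.extend(r.constant_names)
    network = ReactionNetwork(tuple(species), tuple(reactions), tuple(
        name for name in params if name in set(used)))
    return ImportedModel(network=network,
                         parameters={k: params[k]
                                     for k in network.parameter_names})
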