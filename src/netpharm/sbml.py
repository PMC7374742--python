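"""Minimal SBML level-2 reader/writer for the mass-action subset.

Only what mass-action models need is supported: compartments (sizes fold
into rate constants as plain parameters), species with initial
concentrations, global and reaction-local parameters, and reactions whose
kinetic-law MathML reduces — after substituting parameter values — to
``kf * prod(reactants)`` or ``kf * prod(reactants) - kr * prod(products)``
with the reaction's declared stoichiometries.  Anything else is rejected
with an error naming the reaction, rather than silently misread.
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp
from lxml import etree

from .kinetics import KineticModel, Reaction

__all__ = ["read_sbml", "write_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# ---------------------------------------------------------------- writing

def write_sbml(model: KineticModel, path: str | Path) -> None:
    """Serialize a mass-action model as SBML level 2 version 4."""
    model.validate()
    nsmap = {None: SBML_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap, level="2", version="4")
    mdl = etree.SubElement(root, _q("model"),
                           id=model.name or "model", name=model.name or "model")
    comps = etree.SubElement(mdl, _q("listOfCompartments"))
    etree.SubElement(comps, _q("compartment"), id="cell", size="1")
    sps = etree.SubElement(mdl, _q("listOfSpecies"))
    for name in sorted(model.species):
        etree.SubElement(sps, _q("species"), id=name, compartment="cell",
                         initialConcentration=repr(float(model.species[name])))
    rxns = etree.SubElement(mdl, _q("listOfReactions"))
    for i, r in enumerate(model.reactions, start=1):
        rid = r.rid or f"r{i}"
        rx = etree.SubElement(rxns, _q("reaction"), id=rid,
                              reversible="true" if r.kr is not None else "false")
        lor = etree.SubElement(rx, _q("listOfReactants"))
        for spname, s in sorted(r.reactants.items()):
            etree.SubElement(lor, _q("speciesReference"), species=spname,
                             stoichiometry=str(int(s)))
        lop = etree.SubElement(rx, _q("listOfProducts"))
        for spname, s in sorted(r.products.items()):
            etree.SubElement(lop, _q("speciesReference"), species=spname,
                             stoichiometry=str(int(s)))
        kl = etree.SubElement(rx, _q("kineticLaw"))
        math = etree.SubElement(kl, _q("math", MATHML_NS),
                                nsmap={None: MATHML_NS})
        math.append(_rate_mathml(r))
        lp = etree.SubElement(kl, _q("listOfParameters"))
        etree.SubElement(lp, _q("parameter"), id="kf", value=repr(float(r.kf)))
        if r.kr is not None:
            etree.SubElement(lp, _q("parameter"), id="kr", value=repr(float(r.kr)))
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def _monomial_mathml(const: str, side: dict) -> etree._Element:
    apply_ = etree.Element(_q("apply", MATHML_NS))
    etree.SubElement(apply_, _q("times", MATHML_NS))
    ci = etree.SubElement(apply_, _q("ci", MATHML_NS))
    ci.text = const
    for spname, s in sorted(side.items()):
        if s == 1:
            el = etree.SubElement(apply_, _q("ci", MATHML_NS))
            el.text = spname
        else:
            pw = etree.SubElement(apply_, _q("apply", MATHML_NS))
            etree.SubElement(pw, _q("power", MATHML_NS))
            base = etree.SubElement(pw, _q("ci", MATHML_NS))
            base.text = spname
            expo = etree.SubElement(pw, _q("cn", MATHML_NS))
            expo.text = str(int(s))
    return apply_


def _rate_mathml(r: Reaction) -> etree._Element:
    fwd = _monomial_mathml("kf", r.reactants)
    if r.kr is None:
        return fwd
    outer = etree.Element(_q("apply", MATHML_NS))
    etree.SubElement(outer, _q("minus", MATHML_NS))
    outer.append(fwd)
    outer.append(_monomial_mathml("kr", r.products))
    return outer


# ---------------------------------------------------------------- reading

def _mathml_to_sympy(node: etree._Element) -> sp.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ValueError("MathML <math> must wrap a single expression")
        return _mathml_to_sympy(children[0])
    if tag == "ci":
        return sp.Symbol(node.text.strip())
    if tag == "cn":
        if node.get("type") == "e-notation":
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return sp.Float(f"{parts[0]}e{parts[1]}")
        text = node.text.strip()
        # keep integral constants exact so stoichiometric powers stay integer
        try:
            return sp.Integer(int(text))
        except ValueError:
            return sp.Float(text)
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_sympy(c) for c in children[1:]]
        if op == "times":
            return sp.Mul(*args)
        if op == "plus":
            return sp.Add(*args)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            return args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        raise ValueError(f"unsupported MathML operator <{op}>")
    raise ValueError(f"unsupported MathML element <{tag}>")


def _mass_action_constants(expr: sp.Expr, reactants: dict, products: dict,
                           species: set, rid: str) -> tuple[float, float | None]:
    """Match a numeric rate polynomial against the mass-action template and
    return (kf, kr).  ``expr`` must contain only species symbols."""
    free = {s.name for s in expr.free_symbols}
    if not free <= species:
        raise ValueError(f"reaction {rid!r}: rate law references unknown "
                         f"symbols {sorted(free - species)}")
    fwd = sp.Mul(*[sp.Symbol(s) ** int(n) for s, n in reactants.items()])
    rev = sp.Mul(*[sp.Symbol(s) ** int(n) for s, n in products.items()])
    poly = sp.expand(expr)
    terms = poly.as_ordered_terms() if poly != 0 else []
    kf = 0.0
    kr: float | None = None
    for term in terms:
        coeff, monom = term.as_coeff_Mul()
        if sp.simplify(monom - fwd) == 0 and coeff > 0:
            kf = float(coeff)
        elif sp.simplify(monom - rev) == 0 and coeff < 0:
            kr = float(-coeff)
        else:
            raise ValueError(
                f"reaction {rid!r}: kinetic law is not mass action "
                f"(unexpected term {term})")
    return kf, kr


def read_sbml(path: str | Path) -> KineticModel:
    """Read an SBML level-2 mass-action model written by :func:`write_sbml`
    or by any tool that stays inside the supported subset."""
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = etree.QName(root).namespace
    if "sbml/level2" not in (ns or ""):
        raise ValueError(f"{path.name}: not an SBML level-2 document")

    def findall(parent, *tags):
        cur = [parent]
        for t in tags:
            nxt = []
            for p in cur:
                nxt.extend(p.findall(_q(t, ns)))
            cur = nxt
        return cur

    mdl = root.find(_q("model", ns))
    if mdl is None:
        raise ValueError(f"{path.name}: no <model> element")
    model = KineticModel(name=mdl.get("id", path.stem))

    global_subs: dict[sp.Symbol, float] = {}
    for comp in findall(mdl, "listOfCompartments", "compartment"):
        global_subs[sp.Symbol(comp.get("id"))] = float(comp.get("size", "1"))
    for par in findall(mdl, "listOfParameters", "parameter"):
        if par.get("value") is None:
            raise ValueError(f"{path.name}: parameter {par.get('id')!r} has no value")
        global_subs[sp.Symbol(par.get("id"))] = float(par.get("value"))

    for spe in findall(mdl, "listOfSpecies", "species"):
        sid = spe.get("id")
        conc = spe.get("initialConcentration", spe.get("initialAmount"))
        if conc is None:
            raise ValueError(f"{path.name}: species {sid!r} has no initial "
                             "concentration")
        model.species[sid] = float(conc)

    species_names = set(model.species)
    for rx in findall(mdl, "listOfReactions", "reaction"):
        rid = rx.get("id", "")
        reactants = {ref.get("species"): int(float(ref.get("stoichiometry", "1")))
                     for ref in findall(rx, "listOfReactants", "speciesReference")}
        products = {ref.get("species"): int(float(ref.get("stoichiometry", "1")))
                    for ref in findall(rx, "listOfProducts", "speciesReference")}
        kl = rx.find(_q("kineticLaw", ns))
        if kl is None:
            raise ValueError(f"{path.name}: reaction {rid!r} has no kinetic law")
        subs = dict(global_subs)
        for par in findall(kl, "listOfParameters", "parameter"):
            subs[sp.Symbol(par.get("id"))] = float(par.get("value"))
        math = kl.find(_q("math", MATHML_NS))
        if math is None:
            raise ValueError(f"{path.name}: reaction {rid!r} has no MathML")
        expr = _mathml_to_sympy(math).subs(subs)
        kf, kr = _mass_action_constants(expr, reactants, products,
                                        species_names, rid)
        model.reactions.append(Reaction(reactants=reactants, products=products,
                                        kf=kf, kr=kr, rid=rid))
    model.validate()
    return model
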