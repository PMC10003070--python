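"""SBML Level 3 export/import of the model.

The writer builds the document directly (lxml), with kinetic laws defined
once as sympy expressions and serialized to content MathML. The reader
evaluates the MathML back into sympy and assembles an ODE right-hand side
from the reactions' stoichiometry, so an export/import round trip exercises
a fully independent formula path (sympy-evaluated kinetic laws vs the
hand-coded rate functions).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import sympy as sp
from sympy.printing.mathml import MathMLContentPrinter
from lxml import etree
from scipy.integrate import solve_ivp

from . import model
from .params import ExternalPools, KineticParameters

__all__ = ["export_sbml", "read_sbml", "integrate_sbml", "symbolic_rates"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_SPECIES = model.METABOLITES           # x1..x9 -> cap..ctp
_EXTERNAL = ("atp", "imp")


def symbolic_rates(p: KineticParameters | None = None,
                   ext: ExternalPools | None = None) -> dict[str, sp.Expr]:
    """The thirteen kinetic laws as sympy expressions.

    Species appear as symbols named after the metabolites (plus ``atp`` and
    ``imp``); parameters appear as symbols with their model names unless
    ``p``/``ext`` are given, in which case numeric values are substituted.
    """
    cap, casp, dho, oro, omp, ump, udp, utp, ctp = sp.symbols(
        " ".join(_SPECIES), nonnegative=True)
    atp, imp = sp.symbols("atp imp", nonnegative=True)
    s = {n: sp.Symbol(n, positive=True) for n in KineticParameters.names()}

    v1 = s["k1"] * (1 + s["d_IMP"] * imp / s["Ka_IMP1"]) / (
        1 + (ump / s["K_UMP1"]) ** s["h_UMP1"] + imp / s["K_IMP1"]
        + (udp / s["K_UDP1"]) ** s["h_UDP1"] + (utp / s["K_UTP1"]) ** s["h_UTP1"])
    sub2 = (cap / s["Km_CAP2"]) ** s["h_CAP"]
    v2 = (s["k2"] * sub2 / (1 + sub2)
          * (1 + s["d_CTP2"] * ctp / s["K_CTP2"] + s["d_ATP2"] * atp / s["K_ATP2"]
             + s["d_UTP2"] * utp / s["K_UTP2"])
          / (1 + ctp / s["K_CTP2"] + atp / s["K_ATP2"] + utp / s["K_UTP2"]
             + s["w2"] * (ctp / s["K_CTP2"]) * (utp / s["K_UTP2"])))
    v3 = s["k3"] * (casp / s["Km_CAASP3"]) / (1 + casp / s["Km_CAASP3"])
    v4 = ((s["k4f"] * dho / s["Km_DHO4"] - s["k4r"] * oro / s["Km_ORO4"])
          / (s["k4"] * (1 + dho / s["Km_DHO4"])
             * (1 + oro / s["Ki_ORO4"] + oro / s["Km_ORO4"])))
    v5 = s["k5"] * (oro / s["Km_ORO5"]) / (s["k5prpp"] + oro / s["Km_ORO5"])
    v6 = s["k6"] * (omp / s["Km_OMP6"]) / (1 + omp / s["Km_OMP6"])
    v7 = (s["k7"] * ump
          / (s["Km_UMP7"] * (1 + ((1 - s["r"]) * utp / s["K_UTP72"]) ** s["h_UTP7"])
             + ump)
          / (1 + (s["r"] * utp / s["K_UTP71"]) ** s["h_UTP7"]))
    v8 = s["k8"] * udp / (s["Km_UDP8"] + udp)
    v9 = (s["k9"] * utp ** s["h_UTP9"]
          / (s["Km_UTP9"] ** s["h_UTP9"] * (1 + ctp / s["K_CTP9"])
             + utp ** s["h_UTP9"]))
    laws = {"v1": v1, "v2": v2, "v3": v3, "v4": v4, "v5": v5, "v6": v6,
            "v7": v7, "v8": v8, "v9": v9,
            "v10": s["k10"] * utp, "v11": s["k11"] * ctp,
            "v12": s["k23"] * ctp, "v15": s["k22"] * udp}
    if p is not None:
        subs = {s[n]: sp.Float(p[n]) for n in KineticParameters.names()}
        if ext is not None:
            subs[atp] = sp.Float(ext.atp)
            subs[imp] = sp.Float(ext.imp)
        laws = {k: v.subs(subs) for k, v in laws.items()}
    return laws


#: reaction name -> (reactants, products); outflows have no products
_REACTIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "v1": ((), ("cap",)),
    "v2": (("cap",), ("casp",)),
    "v3": (("casp",), ("dho",)),
    "v4": (("dho",), ("oro",)),
    "v5": (("oro",), ("omp",)),
    "v6": (("omp",), ("ump",)),
    "v7": (("ump",), ("udp",)),
    "v8": (("udp",), ("utp",)),
    "v9": (("utp",), ("ctp",)),
    "v10": (("utp",), ()),
    "v11": (("ctp",), ()),
    "v12": (("ctp",), ()),
    "v15": (("udp",), ()),
}


class _PlainSymbolMathMLPrinter(MathMLContentPrinter):
    """Content-MathML printer emitting symbol names verbatim in <ci>.

    The stock printer typesets underscored names as subscript markup, which
    is presentation MathML and breaks ci-based identifier lookup.
    """

    def _print_Symbol(self, symbol):
        ci = self.dom.createElement(self.mathml_tag(symbol))
        ci.appendChild(self.dom.createTextNode(symbol.name))
        return ci


def _mathml_content(expr: sp.Expr) -> etree._Element:
    xml = _PlainSymbolMathMLPrinter().doprint(expr)
    return etree.fromstring(
        f'<math xmlns="{MATHML_NS}">{xml}</math>'.encode())


def export_sbml(p: KineticParameters, ext: ExternalPools,
                path: str | Path,
                x0=None, model_id: str = "pyrimidine_biosynthesis") -> None:
    """Write the model as an SBML L3V1 document with MathML kinetic laws.

    Nine pathway species plus boundary species for the external ATP/IMP
    pools; one reaction per enzymatic step and outflow. ``x0`` sets species
    initial concentrations (default: the empty pathway).
    """
    x0 = np.zeros(9) if x0 is None else np.asarray(x0, float)
    nsmap = {None: SBML_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="3", version="1")
    mdl = etree.SubElement(root, "model", id=model_id,
                           substanceUnits="millimole", timeUnits="second",
                           extentUnits="millimole", volumeUnits="litre")
    lc = etree.SubElement(mdl, "listOfCompartments")
    etree.SubElement(lc, "compartment", id="cell", size="1", constant="true",
                     spatialDimensions="3")
    ls = etree.SubElement(mdl, "listOfSpecies")
    for name, v in zip(_SPECIES, x0):
        etree.SubElement(ls, "species", id=name, compartment="cell",
                         initialConcentration=repr(float(v)),
                         hasOnlySubstanceUnits="false",
                         boundaryCondition="false", constant="false")
    for name, v in zip(_EXTERNAL, (ext.atp, ext.imp)):
        etree.SubElement(ls, "species", id=name, compartment="cell",
                         initialConcentration=repr(float(v)),
                         hasOnlySubstanceUnits="false",
                         boundaryCondition="true", constant="true")
    lp = etree.SubElement(mdl, "listOfParameters")
    for name, value in p.items():
        etree.SubElement(lp, "parameter", id=name, value=repr(float(value)),
                         constant="true")
    laws = symbolic_rates()                       # symbolic: parameters by id
    lr = etree.SubElement(mdl, "listOfReactions")
    for rid, (reactants, products) in _REACTIONS.items():
        rxn = etree.SubElement(lr, "reaction", id=rid, reversible="true",
                               fast="false")
        if reactants:
            lref = etree.SubElement(rxn, "listOfReactants")
            for sp_id in reactants:
                etree.SubElement(lref, "speciesReference", species=sp_id,
                                 stoichiometry="1", constant="true")
        if products:
            lpro = etree.SubElement(rxn, "listOfProducts")
            for sp_id in products:
                etree.SubElement(lpro, "speciesReference", species=sp_id,
                                 stoichiometry="1", constant="true")
        kl = etree.SubElement(rxn, "kineticLaw")
        kl.append(_mathml_content(laws[rid]))
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


# -- import ------------------------------------------------------------------

_MML_OPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
    "minus": lambda *a: a[0] - a[1] if len(a) == 2 else -a[0],
    "divide": lambda a, b: a / b,
    "power": lambda a, b: a ** b,
    "root": lambda a, b=None: sp.sqrt(a) if b is None else a ** (1 / b),
    "exp": sp.exp, "ln": sp.log, "abs": sp.Abs,
}


def _mathml_to_sympy(node: etree._Element, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ValueError("math element must have one child")
        return _mathml_to_sympy(children[0], symbols)
    if tag == "ci":
        name = node.text.strip()
        return symbols.setdefault(name, sp.Symbol(name))
    if tag == "cn":
        t = node.get("type", "real")
        if t == "e-notation":
            mant = float(node.text.strip())
            sep = node.find(f"{{{MATHML_NS}}}sep")
            return sp.Float(mant * 10.0 ** float(sep.tail.strip()))
        if t == "integer":
            return sp.Integer(int(node.text.strip()))
        return sp.Float(float(node.text.strip()))
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_sympy(c, symbols) for c in children[1:]]
        if op not in _MML_OPS:
            raise ValueError(f"unsupported MathML operator <{op}>")
        return _MML_OPS[op](*args)
    raise ValueError(f"unsupported MathML element <{tag}>")


def read_sbml(path: str | Path) -> dict:
    """Parse an SBML document written by :func:`export_sbml`.

    Returns a dict with species ids/initial concentrations, boundary species,
    parameter values, and per-reaction (stoichiometry, sympy kinetic law).
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = {"s": SBML_NS}
    species, boundary, init = [], {}, {}
    for el in root.findall(".//s:listOfSpecies/s:species", ns):
        sid = el.get("id")
        conc = float(el.get("initialConcentration", "0"))
        if el.get("boundaryCondition") == "true":
            boundary[sid] = conc
        else:
            species.append(sid)
            init[sid] = conc
    parameters = {el.get("id"): float(el.get("value"))
                  for el in root.findall(".//s:listOfParameters/s:parameter", ns)}
    reactions = {}
    symbols: dict[str, sp.Symbol] = {}
    for rxn in root.findall(".//s:listOfReactions/s:reaction", ns):
        rid = rxn.get("id")
        stoich: dict[str, float] = {}
        for ref in rxn.findall("s:listOfReactants/s:speciesReference", ns):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) - \
                float(ref.get("stoichiometry", "1"))
        for ref in rxn.findall("s:listOfProducts/s:speciesReference", ns):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) + \
                float(ref.get("stoichiometry", "1"))
        math = rxn.find("s:kineticLaw/{%s}math" % MATHML_NS, ns)
        if math is None:
            raise ValueError(f"reaction {rid} has no kinetic law")
        reactions[rid] = (stoich, _mathml_to_sympy(math, symbols))
    return {"species": species, "initial": init, "boundary": boundary,
            "parameters": parameters, "reactions": reactions}


def integrate_sbml(path: str | Path, t_end: float, report_step: float = 30.0,
                   rtol: float = 1e-8, atol: float = 1e-12):
    """Simulate an SBML file via its MathML kinetic laws (lambdified).

    Returns (times, states, species). The right-hand side is assembled from
    the document alone: stoichiometry x kinetic laws with parameter and
    boundary-species values substituted.
    """
    doc = read_sbml(path)
    species = doc["species"]
    subs = {sp.Symbol(k): sp.Float(v) for k, v in doc["parameters"].items()}
    subs.update({sp.Symbol(k): sp.Float(v) for k, v in doc["boundary"].items()})
    sym = [sp.Symbol(name) for name in species]
    dxdt = [sp.Integer(0)] * len(species)
    for stoich, law in doc["reactions"].values():
        law_n = law.subs(subs)
        for sp_id, coef in stoich.items():
            i = species.index(sp_id)
            dxdt[i] = dxdt[i] + coef * law_n
    funcs = [sp.lambdify(sym, expr, modules="numpy") for expr in dxdt]

    def f(t, x):
        xc = np.clip(x, 0.0, None)
        return [fn(*xc) for fn in funcs]

    t_eval = np.arange(0.0, t_end + 0.5 * report_step, report_step)
    t_eval = t_eval[t_eval <= t_end]
    x0 = [doc["initial"][name] for name in species]
    sol = solve_ivp(f, (0.0, t_end), x0, t_eval=t_eval, rtol=rtol, atol=atol,
                    method="LSODA")
    if not sol.success:
        raise RuntimeError(f"SBML simulation failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, 0.0, None), species
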