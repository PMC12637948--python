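"""Minimal SBML Level 3 Version 2 export of a parameterized kinetic model.

Writes species, global parameters, and reactions with content-MathML kinetic
laws (substance in mM, time in minutes). The writer covers the built-in rate
laws (fdh, bdh, decomp); user-defined callables cannot be serialized and
raise. A small reader recovers species ids and parameter values for
round-trip checks.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping

from .model import KineticModel

__all__ = ["export_sbml", "read_sbml_params", "read_sbml_species"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml_expr(expr) -> ET.Element:
    """Content MathML for a nested prefix expression.

    ``expr`` is a string (symbol), a number, or a tuple
    ``(op, arg1, arg2, ...)`` with op in {+, -, *, /}.
    """
    if isinstance(expr, str):
        el = ET.Element(f"{{{MATHML_NS}}}ci")
        el.text = f" {expr} "
        return el
    if isinstance(expr, (int, float)):
        el = ET.Element(f"{{{MATHML_NS}}}cn")
        el.text = f" {expr} "
        return el
    op, *args = expr
    apply_el = ET.Element(f"{{{MATHML_NS}}}apply")
    op_tag = {"+": "plus", "-": "minus", "*": "times", "/": "divide"}[op]
    apply_el.append(ET.Element(f"{{{MATHML_NS}}}{op_tag}"))
    for a in args:
        apply_el.append(_mathml_expr(a))
    return apply_el


def _rate_expression(model: KineticModel, rxn) -> tuple:
    """Prefix expression of a built-in rate law in mM/min."""
    p = rxn.params
    role = lambda r: model.species_by_role(r).id
    if rxn.rate_law == "fdh":
        A, B, Q = role("A"), role("B"), role("Q")
        num = ("*", 60.0, p["kcat"], A, B, p["E"])
        den = (
            "+",
            ("*", p["KIA"], p["KMB"]),
            ("*", p["KMB"], A),
            ("*", p["KMA"], B),
            ("*", A, B),
            ("*", ("/", ("*", p["KIA"], p["KMB"]), p["KIQ"]), Q),
            ("*", ("/", p["KMA"], p["KIQ"]), B, Q),
        )
        return ("/", num, den)
    if rxn.rate_law == "bdh":
        S, Q, P, A = role("S"), role("Q"), role("P"), role("A")
        fwd = ("*", p["kcatf"], ("/", S, p["KMS"]), ("/", Q, p["KMQ"]))
        rev = ("*", p["kcatr"], ("/", P, p["KMP"]), ("/", A, p["KMA"]))
        num = ("*", 60.0, p["E"], ("-", fwd, rev))
        den = (
            "-",
            ("+",
             ("*", ("+", 1.0, ("/", S, p["KMS"])), ("+", 1.0, ("/", Q, p["KMQ"]))),
             ("*", ("+", 1.0, ("/", P, p["KMP"])), ("+", 1.0, ("/", A, p["KMA"])))),
            1.0,
        )
        return ("/", num, den)
    if rxn.rate_law == "decomp":
        return ("*", p["kdq"], role("Q"))
    raise ValueError(
        f"reaction {rxn.id}: rate law {rxn.rate_law!r} cannot be exported to SBML"
    )


def export_sbml(
    model: KineticModel,
    params: Mapping[str, float],
    path=None,
    model_id: str = "cfkinetics_model",
) -> str:
    """Serialize the model with the given parameter values to SBML L3V2.

    Returns the XML text; also writes it to ``path`` when given.
    """
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    mdl = ET.SubElement(
        sbml, f"{{{SBML_NS}}}model",
        {"id": model_id, "substanceUnits": "millimole", "timeUnits": "minute"},
    )

    compartments = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        compartments, f"{{{SBML_NS}}}compartment",
        {"id": "c", "size": "1", "constant": "true", "spatialDimensions": "3"},
    )

    species_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for sp in model.species:
        ET.SubElement(
            species_el, f"{{{SBML_NS}}}species",
            {
                "id": sp.id, "name": sp.name, "compartment": "c",
                "initialConcentration": "0",
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false", "constant": "false",
            },
        )

    params_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name, value in sorted(params.items()):
        ET.SubElement(
            params_el, f"{{{SBML_NS}}}parameter",
            {"id": name, "value": repr(float(value)), "constant": "true"},
        )

    reactions_el = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for rxn in model.reactions:
        r_el = ET.SubElement(
            reactions_el, f"{{{SBML_NS}}}reaction",
            {"id": rxn.id, "reversible": "true" if rxn.rate_law == "bdh" else "false"},
        )
        reactants = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
        products = ET.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
        for sid, coef in rxn.stoichiometry.items():
            parent = reactants if coef < 0 else products
            ET.SubElement(
                parent, f"{{{SBML_NS}}}speciesReference",
                {"species": sid, "stoichiometry": repr(abs(float(coef))),
                 "constant": "true"},
            )
        kl = ET.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        math_el.append(_mathml_expr(_rate_expression(model, rxn)))

    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_sbml_params(source) -> dict:
    """Parameter id -> value from an SBML document (path or XML text)."""
    root = _parse(source)
    out = {}
    for el in root.iter(f"{{{SBML_NS}}}parameter"):
        out[el.get("id")] = float(el.get("value"))
    return out


def read_sbml_species(source) -> list:
    """Species ids from an SBML document (path or XML text)."""
    root = _parse(source)
    return [el.get("id") for el in root.iter(f"{{{SBML_NS}}}species")]


def _parse(source) -> ET.Element:
    text = source
    if not str(source).lstrip().startswith("<"):
        with open(source) as fh:
            text = fh.read()
    return ET.fromstring(text)
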