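"""Minimal SBML Level 3 Version 2 export.

Writes one compartment, every species with its initial concentration, every
parameter as a constant, and every reaction with its kinetic law as content
MathML (produced by sympy from the compiled rate-law expressions).  Models
with time-varying rules export the rule symbols as non-constant parameters;
the waveforms themselves are simulation-side forcing and are not encoded.
Import is intentionally not supported.
"""

from __future__ import annotations

from pathlib import Path

import sympy
from lxml import etree

from .circuit import CompiledModel

__all__ = ["export_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml(expr_text: str, symbols) -> etree._Element:
    local = {name: sympy.Symbol(name) for name in symbols}
    local["t"] = sympy.Symbol("t")
    try:
        expr = sympy.parse_expr(expr_text, local_dict=local, evaluate=False)
    except (SyntaxError, TypeError, ValueError) as exc:
        raise ValueError(f"rate law not expressible in SBML: {expr_text!r}") from exc
    content = sympy.mathml(expr)
    # sympy renders underscored names as subscripted symbols with an "mml"
    # presentation prefix; declare it so the fragment parses standalone
    math = etree.fromstring(
        f'<math xmlns="{MATHML_NS}" xmlns:mml="{MATHML_NS}">{content}</math>'.encode()
    )
    return math


def export_sbml(model: CompiledModel, path) -> None:
    """Write ``model`` to ``path`` as an SBML L3V2 document."""
    nsmap = {None: SBML_NS}
    sbml = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(sbml, "model", id="grnsim_model")

    comps = etree.SubElement(mdl, "listOfCompartments")
    etree.SubElement(
        comps, "compartment", id="cell", constant="true", size="1", spatialDimensions="3"
    )

    if model.species:
        los = etree.SubElement(mdl, "listOfSpecies")
        for sp, v in zip(model.species, model.init):
            etree.SubElement(
                los,
                "species",
                id=sp,
                compartment="cell",
                initialConcentration=repr(float(v)),
                hasOnlySubstanceUnits="false",
                boundaryCondition="false",
                constant="false",
            )

    rule_symbols = {r.symbol for r in model.rules}
    if model.param_names:
        lop = etree.SubElement(mdl, "listOfParameters")
        for name, v in zip(model.param_names, model.param_values):
            etree.SubElement(
                lop,
                "parameter",
                id=name,
                value=repr(float(v)),
                constant="false" if name in rule_symbols else "true",
            )

    symbols = list(model.species) + list(model.param_names)
    if model.reactions:
        lor = etree.SubElement(mdl, "listOfReactions")
        for i, rxn in enumerate(model.reactions):
            r = etree.SubElement(
                lor, "reaction", id=f"r{i}_{rxn.name}", reversible="false"
            )
            reactants = {s: -c for s, c in rxn.stoich.items() if c < 0}
            products = {s: c for s, c in rxn.stoich.items() if c > 0}
            if reactants:
                lr = etree.SubElement(r, "listOfReactants")
                for s, c in reactants.items():
                    etree.SubElement(
                        lr,
                        "speciesReference",
                        species=s,
                        stoichiometry=repr(float(c)),
                        constant="true",
                    )
            if products:
                lp = etree.SubElement(r, "listOfProducts")
                for s, c in products.items():
                    etree.SubElement(
                        lp,
                        "speciesReference",
                        species=s,
                        stoichiometry=repr(float(c)),
                        constant="true",
                    )
            kl = etree.SubElement(r, "kineticLaw")
            kl.append(_mathml(rxn.rate_law, symbols))

    doc = etree.ElementTree(sbml)
    doc.write(
        str(Path(path)), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
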