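"""SBML Level 3 Version 1 export of a :class:`PathwayModel`.

A plain XML writer: kinetic laws become explicit MathML rate
expressions with local parameters, fixed pools become boundary/constant
species.  Intended for interchange and cross-checking against other
simulators, not for validation.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .model import (
    ConstantFlux,
    MassActionIrrev,
    MassActionRev,
    PathwayModel,
    SaturatingIrrev,
)

__all__ = ["export_sbml", "sbml_string"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_COMPARTMENT = "cytoplasm"


def _ci(parent, name):
    e = ET.SubElement(parent, f"{{{_MATHML_NS}}}ci")
    e.text = f" {name} "


def _times(parent, names):
    if len(names) == 1:
        _ci(parent, names[0])
        return
    apply_ = ET.SubElement(parent, f"{{{_MATHML_NS}}}apply")
    ET.SubElement(apply_, f"{{{_MATHML_NS}}}times")
    for n in names:
        _ci(apply_, n)


def _species_factors(side) -> list[str]:
    out = []
    for sid, n in side.items():
        out.extend([sid] * n)
    return out


def _law_math(reaction) -> ET.Element:
    math = ET.Element(f"{{{_MATHML_NS}}}math")
    law = reaction.law
    if isinstance(law, ConstantFlux):
        _ci(math, "v0")
    elif isinstance(law, MassActionIrrev):
        _times(math, ["k"] + _species_factors(reaction.substrates))
    elif isinstance(law, MassActionRev):
        apply_ = ET.SubElement(math, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(apply_, f"{{{_MATHML_NS}}}minus")
        _times(apply_, ["kf"] + _species_factors(reaction.substrates))
        _times(apply_, ["kr"] + _species_factors(reaction.products))
    elif isinstance(law, SaturatingIrrev):
        sid = next(iter(reaction.substrates))
        apply_ = ET.SubElement(math, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(apply_, f"{{{_MATHML_NS}}}divide")
        _times(apply_, ["vmax", sid])
        plus = ET.SubElement(apply_, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(plus, f"{{{_MATHML_NS}}}plus")
        _ci(plus, "km")
        _ci(plus, sid)
    else:
        raise TypeError(f"no MathML template for law {law.form!r}")
    return math


def sbml_string(model: PathwayModel, model_id: str = "thf_biosynthesis") -> str:
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("math", _MATHML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "1"})
    mdl = ET.SubElement(sbml, f"{{{_SBML_NS}}}model", {"id": model_id})

    comps = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{_SBML_NS}}}compartment",
        {"id": _COMPARTMENT, "size": "1", "constant": "true", "spatialDimensions": "3"},
    )

    sp_list = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfSpecies")
    for s in model.species:
        ET.SubElement(
            sp_list,
            f"{{{_SBML_NS}}}species",
            {
                "id": s.id,
                "name": s.name,
                "compartment": _COMPARTMENT,
                "initialConcentration": repr(s.init_conc),
                "boundaryCondition": "true" if s.fixed else "false",
                "constant": "true" if s.fixed else "false",
                "hasOnlySubstanceUnits": "false",
            },
        )

    rx_list = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rx = ET.SubElement(
            rx_list,
            f"{{{_SBML_NS}}}reaction",
            {"id": r.id, "reversible": "true" if isinstance(r.law, MassActionRev) else "false",
             "fast": "false"},
        )
        if r.substrates:
            refs = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
            for sid, n in r.substrates.items():
                ET.SubElement(
                    refs, f"{{{_SBML_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": str(n), "constant": "true"},
                )
        if r.products:
            refs = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
            for sid, n in r.products.items():
                ET.SubElement(
                    refs, f"{{{_SBML_NS}}}speciesReference",
                    {"species": sid, "stoichiometry": str(n), "constant": "true"},
                )
        kl = ET.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        kl.append(_law_math(r))
        params = ET.SubElement(kl, f"{{{_SBML_NS}}}listOfLocalParameters")
        for name, value in r.law.parameters().items():
            ET.SubElement(
                params, f"{{{_SBML_NS}}}localParameter",
                {"id": name, "value": repr(value)},
            )

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


def export_sbml(model: PathwayModel, path, model_id: str = "thf_biosynthesis") -> None:
    with open(path, "w") as fh:
        fh.write(sbml_string(model, model_id))
        fh.write("\n")
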