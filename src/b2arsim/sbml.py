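"""Export of the reaction network to SBML Level 3 for cross-simulator checks.

Valid only for a fixed ligand environment: the resolved rate table is
constant within a protocol segment, so the network is a plain first-order
mass-action system that any SBML-capable engine can integrate.  The
document is written directly as SBML L3V2 core XML with one irreversible
reaction per directed edge and a local mass-action kinetic law k * S.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping

from .network import REACTIONS, SPECIES

__all__ = ["export_sbml", "SBML_NS", "MATHML_NS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class UnsupportedExportError(ValueError):
    """The environment is not resolvable to constant rates."""


def export_sbml(
    rates: Mapping[str, float],
    initial_state: Mapping[str, float] | None = None,
    model_id: str = "b2ar_grk_regulation",
) -> str:
    """Render the network under a resolved rate table as an SBML document.

    Parameters
    ----------
    rates
        Fully resolved rate table (from
        :func:`~b2arsim.network.effective_rates`); must contain every rate
        key used by the reaction table, including ``k2f``.
    initial_state
        Species initial amounts; defaults to the naive state (Rs = 1).
    """
    missing = {key for _, _, key in REACTIONS} - set(rates)
    if missing:
        raise UnsupportedExportError(
            f"rate table is missing resolved constant(s): {', '.join(sorted(missing))}"
        )
    init = {name: 0.0 for name in SPECIES}
    init["Rs"] = 1.0
    if initial_state:
        init.update({k: float(v) for k, v in initial_state.items()})

    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    compartments = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        compartments,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "size": "1", "constant": "true"},
    )

    species_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for name in SPECIES:
        ET.SubElement(
            species_list,
            f"{{{SBML_NS}}}species",
            {
                "id": name,
                "compartment": "cell",
                "initialAmount": repr(init[name]),
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    reactions_list = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for i, (substrate, product, key) in enumerate(REACTIONS, start=1):
        rxn = ET.SubElement(
            reactions_list,
            f"{{{SBML_NS}}}reaction",
            {"id": f"r{i:02d}_{key}", "reversible": "false"},
        )
        reactants = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfReactants")
        ET.SubElement(
            reactants,
            f"{{{SBML_NS}}}speciesReference",
            {"species": substrate, "stoichiometry": "1", "constant": "true"},
        )
        products = ET.SubElement(rxn, f"{{{SBML_NS}}}listOfProducts")
        ET.SubElement(
            products,
            f"{{{SBML_NS}}}speciesReference",
            {"species": product, "stoichiometry": "1", "constant": "true"},
        )
        law = ET.SubElement(rxn, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(law, f"{{{MATHML_NS}}}math")
        apply = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(apply, f"{{{MATHML_NS}}}times")
        ci_k = ET.SubElement(apply, f"{{{MATHML_NS}}}ci")
        ci_k.text = f" {key}_r{i:02d} "
        ci_s = ET.SubElement(apply, f"{{{MATHML_NS}}}ci")
        ci_s.text = f" {substrate} "
        params = ET.SubElement(law, f"{{{SBML_NS}}}listOfLocalParameters")
        ET.SubElement(
            params,
            f"{{{SBML_NS}}}localParameter",
            {"id": f"{key}_r{i:02d}", "value": repr(float(rates[key]))},
        )

    ET.indent(sbml)
    body = ET.tostring(sbml, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
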