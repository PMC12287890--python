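"""SBML level-3 serialisation of consortium models.

Writes and reads SBML L3V2 core documents with compartments, species and
reactions; the chemiosmotic bookkeeping that core SBML has no slot for
(ion translocation nu+, occurrence numbers chi_E, proteome fractions phi,
kinetic capacities, formal compositions) travels in a dedicated annotation
namespace so that ``read(write(model))`` reproduces the model field by
field.
"""

from __future__ import annotations

import json
from pathlib import Path

from lxml import etree

from .model_core import (
    AggregateGeometry,
    CellModel,
    ConsortiumModel,
    Enzyme,
    Metabolite,
    Reaction,
)

__all__ = ["write_model_sbml", "read_model_sbml", "SBMLError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
ANNO_NS = "urn:aomsr:annotations:v1"
_S = "{%s}" % SBML_NS
_A = "{%s}" % ANNO_NS


class SBMLError(ValueError):
    """Malformed or unsupported SBML input."""


def _sid(species_id: str) -> str:
    """Species id -> valid SBML SId (bijective)."""
    return species_id.replace("@", "_AT_").replace("+", "_plus")


def _unsid(sid: str) -> str:
    return sid.replace("_AT_", "@").replace("_plus", "+")


def _f(x: float) -> str:
    return repr(float(x))


def write_model_sbml(model: ConsortiumModel, path: str | Path) -> None:
    root = etree.Element(_S + "sbml", nsmap={None: SBML_NS, "aomsr": ANNO_NS})
    root.set("level", "3")
    root.set("version", "2")
    mdl = etree.SubElement(root, _S + "model")
    mdl.set("id", "consortium")

    anno = etree.SubElement(mdl, _S + "annotation")
    meta = etree.SubElement(anno, _A + "consortium")
    meta.set("temperature", _f(model.temperature))
    meta.set("ph", _f(model.ph))
    meta.set("f_g", _f(model.f_g))
    meta.set("cell_water", _f(model.cell_water))
    meta.set("diet_carrier", json.dumps(list(model.diet_carrier)))
    geom = etree.SubElement(meta, _A + "geometry")
    geom.set("diameter", _f(model.geometry.diameter))
    geom.set("architecture", model.geometry.architecture)
    geom.set("cell_density", _f(model.geometry.cell_density))
    geom.set("mass_transfer", json.dumps(dict(model.geometry.mass_transfer)))
    for cname, cell in model.cells.items():
        ce = etree.SubElement(meta, _A + "cell")
        ce.set("name", cname)
        ce.set("membrane_potential", _f(cell.membrane_potential))
        ce.set("membrane_capacitance", _f(cell.membrane_capacitance))
        ce.set("ions_per_atp", str(cell.ions_per_atp))
        ce.set("substrate_id", cell.substrate_id)
        ce.set("atpase_id", cell.atpase_id)
        ce.set("pathway_chi", json.dumps(dict(cell.pathway_chi)))
        ce.set("membrane_pool_cap", _f(cell.membrane_pool_cap))
        ce.set("cytoplasm_pool_cap", _f(cell.cytoplasm_pool_cap))
        ce.set("protein_per_gdw", _f(cell.protein_per_gdw))

    comps = etree.SubElement(mdl, _S + "listOfCompartments")
    seen = {m.compartment for m in model.metabolites.values()}
    for comp in sorted(seen):
        c = etree.SubElement(comps, _S + "compartment")
        c.set("id", comp)
        c.set("constant", "true")
        c.set("size", "1")

    sps = etree.SubElement(mdl, _S + "listOfSpecies")
    for met in model.metabolites.values():
        s = etree.SubElement(sps, _S + "species")
        s.set("id", _sid(met.id))
        s.set("compartment", met.compartment)
        s.set("initialConcentration", _f(met.concentration))
        s.set("constant", "true" if met.clamped else "false")
        s.set("boundaryCondition", "true" if met.clamped else "false")
        s.set("hasOnlySubstanceUnits", "false")
        sa = etree.SubElement(etree.SubElement(s, _S + "annotation"),
                              _A + "species")
        sa.set("composition", json.dumps(dict(met.composition)))
        sa.set("charge", _f(met.charge))

    rxns = etree.SubElement(mdl, _S + "listOfReactions")
    for cname, cell in model.cells.items():
        for rxn in cell.reactions:
            r = etree.SubElement(rxns, _S + "reaction")
            r.set("id", f"{cname}__{rxn.id}")
            r.set("reversible", "true")
            ra = etree.SubElement(etree.SubElement(r, _S + "annotation"),
                                  _A + "reaction")
            ra.set("cell", cname)
            ra.set("kind", rxn.kind)
            ra.set("delta_g0_prime", _f(rxn.delta_g0_prime))
            ra.set("nu_plus", _f(rxn.nu_plus))
            ra.set("nu_plus_max", _f(rxn.nu_plus_max))
            ra.set("ion", rxn.ion)
            ra.set("chi_e", _f(rxn.chi_e))
            ra.set("n_electrons", str(rxn.n_electrons))
            if rxn.rate_constant is not None:
                ra.set("rate_constant", _f(rxn.rate_constant))
            enz = cell.enzymes.get(rxn.id)
            if enz is not None:
                ea = etree.SubElement(ra, _A + "enzyme")
                ea.set("phi", _f(enz.phi))
                ea.set("phi_max", _f(enz.phi_max))
                ea.set("kcat_fwd", _f(enz.kcat_fwd))
                ea.set("molar_mass", _f(enz.molar_mass))
                ea.set("km_map", json.dumps(dict(enz.km_map)))
            reac = etree.SubElement(r, _S + "listOfReactants")
            prod = etree.SubElement(r, _S + "listOfProducts")
            for sid, nu in rxn.equation.items():
                parent = reac if nu < 0 else prod
                sr = etree.SubElement(parent, _S + "speciesReference")
                sr.set("species", _sid(sid))
                sr.set("stoichiometry", _f(abs(nu)))
                sr.set("constant", "true")

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def read_model_sbml(path: str | Path) -> ConsortiumModel:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SBMLError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != _S + "sbml":
        raise SBMLError(f"root element is {root.tag!r}, expected SBML level 3")
    mdl = root.find(_S + "model")
    if mdl is None:
        raise SBMLError("missing <model> element")

    comp_ids = {c.get("id") for c in
                mdl.findall(f"{_S}listOfCompartments/{_S}compartment")}

    meta = mdl.find(f"{_S}annotation/{_A}consortium")
    if meta is None:
        raise SBMLError("missing consortium annotation block")

    metabolites: dict[str, Metabolite] = {}
    for s in mdl.findall(f"{_S}listOfSpecies/{_S}species"):
        comp = s.get("compartment")
        if comp not in comp_ids:
            raise SBMLError(
                f"species {s.get('id')!r} references unknown compartment "
                f"{comp!r}")
        sa = s.find(f"{_S}annotation/{_A}species")
        composition = json.loads(sa.get("composition")) if sa is not None else {}
        charge = float(sa.get("charge", 0.0)) if sa is not None else 0.0
        sid = _unsid(s.get("id"))
        metabolites[sid] = Metabolite(
            id=sid, compartment=comp,
            concentration=float(s.get("initialConcentration")),
            clamped=s.get("constant") == "true",
            composition=composition, charge=charge,
        )

    cell_meta = {c.get("name"): c for c in meta.findall(_A + "cell")}
    cell_reactions: dict[str, list[Reaction]] = {n: [] for n in cell_meta}
    cell_enzymes: dict[str, dict[str, Enzyme]] = {n: {} for n in cell_meta}
    for r in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        ra = r.find(f"{_S}annotation/{_A}reaction")
        if ra is None:
            raise SBMLError(f"reaction {r.get('id')!r} lacks its annotation")
        cname = ra.get("cell")
        rid = r.get("id").split("__", 1)[1]
        equation: dict[str, float] = {}
        for sr in r.findall(f"{_S}listOfReactants/{_S}speciesReference"):
            equation[_unsid(sr.get("species"))] = -float(sr.get("stoichiometry"))
        for sr in r.findall(f"{_S}listOfProducts/{_S}speciesReference"):
            equation[_unsid(sr.get("species"))] = float(sr.get("stoichiometry"))
        rc = ra.get("rate_constant")
        cell_reactions[cname].append(Reaction(
            id=rid, equation=equation, kind=ra.get("kind"),
            delta_g0_prime=float(ra.get("delta_g0_prime")),
            nu_plus=float(ra.get("nu_plus")),
            nu_plus_max=float(ra.get("nu_plus_max", 2.0)),
            ion=ra.get("ion", "H+"), chi_e=float(ra.get("chi_e")),
            n_electrons=int(ra.get("n_electrons", 0)),
            rate_constant=float(rc) if rc is not None else None,
        ))
        ea = ra.find(_A + "enzyme")
        if ea is not None:
            cell_enzymes[cname][rid] = Enzyme(
                reaction_id=rid, phi=float(ea.get("phi")),
                phi_max=float(ea.get("phi_max")),
                kcat_fwd=float(ea.get("kcat_fwd")),
                km_map=json.loads(ea.get("km_map")),
                molar_mass=float(ea.get("molar_mass")),
            )

    cells: dict[str, CellModel] = {}
    for cname, ce in cell_meta.items():
        cells[cname] = CellModel(
            name=cname, reactions=cell_reactions[cname],
            enzymes=cell_enzymes[cname],
            membrane_potential=float(ce.get("membrane_potential")),
            membrane_capacitance=float(ce.get("membrane_capacitance")),
            ions_per_atp=int(ce.get("ions_per_atp")),
            substrate_id=ce.get("substrate_id"),
            atpase_id=ce.get("atpase_id"),
            pathway_chi=json.loads(ce.get("pathway_chi")),
            membrane_pool_cap=float(ce.get("membrane_pool_cap")),
            cytoplasm_pool_cap=float(ce.get("cytoplasm_pool_cap")),
            protein_per_gdw=float(ce.get("protein_per_gdw")),
        )

    geom = meta.find(_A + "geometry")
    geometry = AggregateGeometry(
        diameter=float(geom.get("diameter")),
        architecture=geom.get("architecture"),
        cell_density=float(geom.get("cell_density")),
        mass_transfer=json.loads(geom.get("mass_transfer")),
    )
    return ConsortiumModel(
        metabolites=metabolites, cells=cells, geometry=geometry,
        diet_carrier=tuple(json.loads(meta.get("diet_carrier"))),
        f_g=float(meta.get("f_g")),
        temperature=float(meta.get("temperature")),
        ph=float(meta.get("ph")),
        cell_water=float(meta.get("cell_water")),
    )
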