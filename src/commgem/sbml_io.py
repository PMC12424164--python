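"""SBML Level 3 (FBC) reading and writing.

Only the constraint-based subset is handled: compartments, species with
optional chemical formula and charge, reactions with flux bounds, and the
active FBC objective.  Gene-product associations are kept as raw rule
strings; annotations, SBO terms and kinetics are ignored.

Both common bound encodings are accepted on read: FBC ``lowerFluxBound`` /
``upperFluxBound`` parameter references (the modern form) and legacy
kinetic-law local parameters named ``LOWER_BOUND`` / ``UPPER_BOUND``.
"""

from __future__ import annotations

import os
import re

import libsbml

from .model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    UNBOUNDED,
    format_formula,
    parse_formula,
)

__all__ = ["read_sbml", "write_sbml", "SBMLError"]

BIOMASS_PATTERNS = ("Biomass", "biomass", "EX_Biomass")
NGAM_PATTERNS = ("rxn00062", "ATPM", "NGAM")


class SBMLError(RuntimeError):
    pass


def _guess_extracellular(compartments: dict[str, str]) -> str:
    for cid in compartments:
        if cid == "e" or cid.endswith("_e") or cid.lower().startswith("extracell"):
            return cid
    for cid, name in compartments.items():
        if "extracell" in (name or "").lower():
            return cid
    return next(iter(compartments), "e")


def _find_by_patterns(reactions, patterns) -> str | None:
    for pat in patterns:
        for rid in reactions:
            if pat in rid:
                return rid
    return None


def read_sbml(
    path: str | os.PathLike,
    biomass_patterns=BIOMASS_PATTERNS,
    ngam_patterns=NGAM_PATTERNS,
) -> MetabolicModel:
    """Read an SBML Level 3 file into a :class:`MetabolicModel`.

    Raises :class:`SBMLError` on malformed XML and on reactions that carry
    no flux-bound information (named explicitly in the message).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise SBMLError(f"cannot parse {path}: {msgs[0] if msgs else 'unknown error'}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLError(f"{path} contains no model")

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()
    model.extracellular_id = _guess_extracellular(model.compartments)

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                text = fbc_sp.getChemicalFormula()
                formula = parse_formula(text) if text else {}
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        lb = ub = None
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            if fbc_rxn.isSetLowerFluxBound():
                lb = params.get(fbc_rxn.getLowerFluxBound())
            if fbc_rxn.isSetUpperFluxBound():
                ub = params.get(fbc_rxn.getUpperFluxBound())
        if (lb is None or ub is None) and rxn.isSetKineticLaw():
            kl = rxn.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND" and lb is None:
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND" and ub is None:
                    ub = p.getValue()
        if lb is None or ub is None:
            missing = "lower" if lb is None else "upper"
            raise SBMLError(
                f"reaction {rxn.getId()!r} has no {missing} flux bound"
            )

        gene_rule = None
        if fbc_rxn is not None:
            gpa = fbc_rxn.getGeneProductAssociation()
            if gpa is not None:
                assoc = gpa.getAssociation()
                if assoc is not None:
                    gene_rule = assoc.toInfix() if hasattr(assoc, "toInfix") else None

        model.add_reaction(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_rule=gene_rule,
            )
        )

    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = obj.getFluxObjective(0).getReaction()

    # explicit role ids from model notes (written by write_sbml) win over
    # pattern-based guessing; the literal value "none" marks explicit absence
    notes = sbml_model.getNotesString() if sbml_model.isSetNotes() else ""
    noted = dict(re.findall(r"(biomass_id|ngam_id):\s*([\w.-]+)", notes))

    def role(key: str, patterns) -> str | None:
        if key in noted:
            return None if noted[key] == "none" else noted[key]
        return _find_by_patterns(model.reactions, patterns)

    model.biomass_id = role("biomass_id", biomass_patterns)
    model.ngam_id = role("ngam_id", ngam_patterns)
    if model.objective_id is None:
        model.objective_id = model.biomass_id
    model.validate()
    return model


_BOUND_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def write_sbml(model: MetabolicModel, path: str | os.PathLike) -> None:
    """Write a :class:`MetabolicModel` as SBML Level 3 Version 1 + FBC v2."""
    if not model.reactions:
        raise ModelValidationError("refusing to write a model with no reactions")
    model.validate()

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(False)
    sbml_model.setNotes(
        '<body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>biomass_id: {model.biomass_id or 'none'}</p>"
        f"<p>ngam_id: {model.ngam_id or 'none'}</p>"
        "</body>"
    )

    for cid, name in model.compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setName(name)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula is not None:
            fbc_sp.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    # flux-bound parameters, deduplicated by value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = "fb_" + _BOUND_SANITIZE.sub("_", repr(float(value)))
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        fbc_rxn = sr.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(rxn.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(rxn.upper_bound))

    if model.objective_id:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if ok != 1:
        raise IOError(f"could not write SBML to {path}")
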