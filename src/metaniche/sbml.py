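"""SBML Level 3 (FBC v2) reading and writing.

Models are serialized with the flux-balance-constraints package: per-reaction
bound parameters, an fbc objective marking the biomass reaction, and boundary
exchanges flagged via their single-metabolite stoichiometry. Ensembles travel
as one SBML file plus a sidecar presence-matrix TSV (see
:meth:`metaniche.ensembles.Ensemble.to_tsv`).
"""
from __future__ import annotations

from pathlib import Path

import libsbml

from .errors import ValidationError
from .model import MetabolicModel, Reaction


def _check(code, message: str) -> None:
    if code not in (libsbml.LIBSBML_OPERATION_SUCCESS, None) and isinstance(code, int) and code < 0:
        raise ValidationError(f"libsbml failure while {message} (code {code})")


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as SBML L3V1 with FBC v2 bounds and objective."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted(set(model.metabolites.values()))
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met, comp in sorted(model.metabolites.items()):
        s = sbml_model.createSpecies()
        s.setId(met)
        s.setCompartment(comp)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    bound_values: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_values:
            pid = f"bound_{len(bound_values)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_values[value] = pid
        return bound_values[value]

    exchange_set = set(model.exchange_ids)
    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met, coeff in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.id in exchange_set:
            r.setSBOTerm("SBO:0000627")  # exchange reaction

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(model.biomass_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ValidationError(f"could not write SBML to {path}")


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read a model written by :func:`write_sbml` (or an equivalent FBC file)."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValidationError(
            f"SBML parse errors in {path}: "
            f"{doc.getErrorLog().toString()[:500]}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValidationError(f"no model element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    metabolites = {
        s.getId(): s.getCompartment() or "c"
        for s in (sbml_model.getSpecies(i) for i in range(sbml_model.getNumSpecies()))
    }

    def param_value(pid: str) -> float:
        p = sbml_model.getParameter(pid)
        if p is None:
            raise ValidationError(f"missing flux-bound parameter {pid!r}")
        return p.getValue()

    reactions: list[Reaction] = []
    exchange_ids: list[str] = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lb = param_value(rplug.getLowerFluxBound())
        ub = param_value(rplug.getUpperFluxBound())
        reactions.append(Reaction(r.getId(), stoich, lb, ub))
        is_exchange = r.getSBOTermID() == "SBO:0000627" or (
            len(stoich) == 1 and r.getId().startswith("EX_")
        )
        if is_exchange:
            exchange_ids.append(r.getId())

    biomass_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()
    if biomass_id is None:
        raise ValidationError(f"no active FBC objective in {path}")

    model = MetabolicModel(
        sbml_model.getId() or Path(path).stem,
        metabolites,
        reactions,
        exchange_ids,
        biomass_id,
    )
    model.validate()
    return model
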