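"""SBML Level 3 / FBC v2 import and export.

Genome-scale reconstructions such as Human-GEM are distributed as SBML
Level 3 documents with the Flux Balance Constraints (FBC) extension, which
carries flux bounds, the active objective and gene-product associations.
This module maps such documents onto :class:`~gemko.model.MetabolicModel`.

Only Level 3 with FBC v2 is accepted.  Level 2 files and files without
explicit FBC flux bounds are rejected with a clear message rather than
guessing bounds: silently invented bounds would corrupt every downstream
flux computation.

Identifier conventions: the standard ``M_``/``R_``/``G_`` SID prefixes are
stripped on read and re-added on write, so Human-GEM reaction ids read as
``MAR07517`` rather than ``R_MAR07517``.  Gene products are identified by
their ``label`` attribute when present (Human-GEM stores Ensembl ids
there), else by their SID.  Subsystems are taken from SBML groups when
present, falling back to ``"unassigned"``.
"""

from __future__ import annotations

import math
from pathlib import Path

import libsbml

from .gpr import And, Gene, GprRule, Or, _Node, parse_gpr
from .model import DEFAULT_BOUND, Metabolite, MetabolicModel, Reaction

__all__ = ["SbmlError", "read_sbml", "write_sbml"]


class SbmlError(ValueError):
    """Raised when an SBML document cannot be mapped onto a model."""


def _strip(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _clamp_infinite(value: float) -> float:
    if math.isinf(value):
        return math.copysign(DEFAULT_BOUND, value)
    return value


def _association_to_node(assoc, label_of: dict[str, str]) -> _Node:
    if assoc.isFbcAnd():
        return And(
            tuple(
                _association_to_node(assoc.getAssociation(i), label_of)
                for i in range(assoc.getNumAssociations())
            )
        )
    if assoc.isFbcOr():
        return Or(
            tuple(
                _association_to_node(assoc.getAssociation(i), label_of)
                for i in range(assoc.getNumAssociations())
            )
        )
    if assoc.isGeneProductRef():
        gp_id = assoc.getGeneProduct()
        return Gene(label_of.get(gp_id, _strip(gp_id, "G_")))
    raise SbmlError(f"unsupported GPR association node of type {type(assoc)}")


def _node_to_rule_string(node: _Node) -> str:
    if isinstance(node, Gene):
        return node.name
    if isinstance(node, And):
        return " and ".join(
            f"({_node_to_rule_string(c)})" if isinstance(c, Or)
            else _node_to_rule_string(c)
            for c in node.children
        )
    if isinstance(node, Or):
        return " or ".join(_node_to_rule_string(c) for c in node.children)
    raise SbmlError(f"unsupported node {node!r}")


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML Level 3 + FBC v2 model.

    Raises
    ------
    SbmlError
        On parse failure (naming the offending element), on Level 2 input,
        on a missing FBC plugin, or on a reaction lacking explicit FBC flux
        bounds.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SbmlError(
            f"SBML parse failure: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    if doc.getLevel() < 3:
        raise SbmlError(
            f"SBML Level {doc.getLevel()} is not supported: flux bounds and "
            "objectives require Level 3 with the FBC extension"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SbmlError("document contains no model element")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise SbmlError("model lacks the FBC extension (no bounds/objective)")

    parameters = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }
    label_of = {
        gp.getId(): (gp.getLabel() or _strip(gp.getId(), "G_"))
        for gp in fbc.getListOfGeneProducts()
    }

    compartments = {
        c.getId(): (c.getName() or c.getId())
        for c in sbml_model.getListOfCompartments()
    }
    metabolites = []
    sid_to_met = {}
    boundary_sids: set[str] = set()
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            # boundary species are outside the balanced system
            boundary_sids.add(sp.getId())
            continue
        met_id = _strip(sp.getId(), "M_")
        sid_to_met[sp.getId()] = met_id
        metabolites.append(
            Metabolite(
                id=met_id,
                name=sp.getName() or "",
                compartment=sp.getCompartment(),
            )
        )

    # subsystems from SBML groups, if any
    subsystem_of: dict[str, str] = {}
    groups = sbml_model.getPlugin("groups")
    if groups is not None:
        for g in groups.getListOfGroups():
            label = g.getName() or g.getId()
            for member in g.getListOfMembers():
                subsystem_of[member.getIdRef()] = label

    reactions = []
    for rxn in sbml_model.getListOfReactions():
        rfbc = rxn.getPlugin("fbc")
        if rfbc is None:
            raise SbmlError(f"reaction {rxn.getId()!r} lacks FBC information")
        lb_id, ub_id = rfbc.getLowerFluxBound(), rfbc.getUpperFluxBound()
        if not lb_id or not ub_id:
            raise SbmlError(
                f"reaction {rxn.getId()!r} has no explicit FBC flux bounds; "
                "refusing to guess"
            )
        try:
            lb, ub = parameters[lb_id], parameters[ub_id]
        except KeyError as exc:
            raise SbmlError(
                f"reaction {rxn.getId()!r} references undefined bound "
                f"parameter {exc.args[0]!r}"
            ) from exc

        stoich: dict[str, float] = {}
        for refs, sign in ((rxn.getListOfReactants(), -1.0),
                           (rxn.getListOfProducts(), 1.0)):
            for ref in refs:
                sid = ref.getSpecies()
                if sid in boundary_sids:
                    continue
                if sid not in sid_to_met:
                    raise SbmlError(
                        f"reaction {rxn.getId()!r} references undeclared "
                        f"species {sid!r}"
                    )
                met = sid_to_met[sid]
                stoich[met] = stoich.get(met, 0.0) + sign * ref.getStoichiometry()

        gpa = rfbc.getGeneProductAssociation()
        if gpa is not None:
            node = _association_to_node(gpa.getAssociation(), label_of)
            gpr = GprRule(expression=node, source_text=_node_to_rule_string(node))
        else:
            gpr = GprRule()

        reactions.append(
            Reaction(
                id=_strip(rxn.getId(), "R_"),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=_clamp_infinite(lb),
                upper_bound=_clamp_infinite(ub),
                subsystem=subsystem_of.get(rxn.getId(), "unassigned"),
                gpr=gpr,
            )
        )

    objective_id = None
    active = fbc.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective_id = _strip(active.getFluxObjective(0).getReaction(), "R_")
    if objective_id is None:
        raise SbmlError("model declares no active FBC objective")

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        genes=set(label_of.values()) or None,
        compartments=compartments,
        id=sbml_model.getId() or "model",
    )


# ---------------------------------------------------------------------------
# Export


def _rule_to_association(node: _Node, fbc_assoc_parent, gp_sid_of):
    if isinstance(node, Gene):
        ref = fbc_assoc_parent.createGeneProductRef()
        ref.setGeneProduct(gp_sid_of[node.name])
        return
    if isinstance(node, And):
        inner = fbc_assoc_parent.createAnd()
    elif isinstance(node, Or):
        inner = fbc_assoc_parent.createOr()
    else:  # pragma: no cover
        raise SbmlError(f"unsupported node {node!r}")
    for child in node.children:
        _rule_to_association(child, inner, gp_sid_of)


def _sanitize_sid(raw: str) -> str:
    return "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as SBML Level 3 Version 1 with FBC v2 and groups."""
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id))
    fbc = sm.getPlugin("fbc")
    fbc.setStrict(True)

    for code, name in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(_sanitize_sid(code))
        comp.setName(name)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId("M_" + _sanitize_sid(m.id))
        sp.setName(m.name)
        sp.setCompartment(_sanitize_sid(m.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    gp_sid_of: dict[str, str] = {}
    for gene in sorted(model.genes):
        gp = fbc.createGeneProduct()
        sid = "G_" + _sanitize_sid(gene)
        gp.setId(sid)
        gp.setLabel(gene)
        gp_sid_of[gene] = sid

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"FB_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    subsystem_members: dict[str, list[str]] = {}
    for r in model.reactions:
        rx = sm.createReaction()
        sid = "R_" + _sanitize_sid(r.id)
        rx.setId(sid)
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met_id, coef in r.stoichiometry.items():
            if coef < 0:
                ref = rx.createReactant()
            elif coef > 0:
                ref = rx.createProduct()
            else:
                continue
            ref.setSpecies("M_" + _sanitize_sid(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rfbc.createGeneProductAssociation()
            _rule_to_association(r.gpr.expression, gpa, gp_sid_of)
        subsystem_members.setdefault(r.subsystem, []).append(sid)

    groups = sm.getPlugin("groups")
    for i, (subsystem, members) in enumerate(sorted(subsystem_members.items())):
        g = groups.createGroup()
        g.setId(f"group_{i}")
        g.setName(subsystem)
        g.setKind("partonomy")
        for sid in members:
            member = g.createMember()
            member.setIdRef(sid)

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction("R_" + _sanitize_sid(model.objective_id))
    flux_obj.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SbmlError(f"failed to write SBML to {path}")
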