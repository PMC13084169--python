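"""Constraint-based metabolic network model and its JSON serialization.

The central object is :class:`MetabolicModel`: an ordered collection of
metabolites and reactions with flux bounds, boolean gene-protein-reaction
rules, pathway (subsystem) labels and compartment assignments, plus a
designated growth objective.  The stoichiometric matrix ``S`` (metabolites
x reactions) is a derived view, built on demand as a sparse matrix.

Sign convention: a negative stoichiometric coefficient means the metabolite
is consumed when the reaction runs left-to-right (positive flux); positive
means produced.  Exchange and demand reactions have a single nonzero
coefficient.

The JSON dialect (``"schema": 1``) mirrors the in-memory structure
one-to-one and round-trips exactly::

    {
      "schema": 1,
      "id": "...",
      "compartments": {"l": "lysosome", ...},
      "metabolites": [{"id", "name", "compartment"}, ...],
      "reactions": [{"id", "name", "stoichiometry": {met: coef},
                     "lower_bound", "upper_bound", "subsystem", "gpr"}, ...],
      "genes": [...],
      "objective": "reaction-id"
    }
"""

from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import EMPTY_RULE, GprRule, parse_gpr

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "JsonSchemaError",
    "read_json_model",
    "write_json_model",
    "model_from_dict",
    "model_to_dict",
]

#: Conventional finite proxy for an unbounded flux.
DEFAULT_BOUND = 1000.0

JSON_SCHEMA_VERSION = 1


class ModelValidationError(ValueError):
    """A model violates a structural invariant; lists every problem found."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid model:\n  - " + "\n  - ".join(problems))


class JsonSchemaError(ValueError):
    """A JSON document does not conform to the model schema."""


@dataclass
class Metabolite:
    """A chemical species located in one compartment."""

    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR."""

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = "unassigned"
    gpr: GprRule = field(default_factory=lambda: EMPTY_RULE)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction: exactly one nonzero coefficient."""
        return sum(1 for c in self.stoichiometry.values() if c != 0) == 1


class MetabolicModel:
    """A stoichiometric network with bounds, GPRs and a growth objective.

    Parameters
    ----------
    metabolites, reactions
        Ordered collections defining the rows and columns of ``S``.
    objective_id
        Reaction id of the growth (biomass) objective; must be present.
    genes
        Declared gene set.  If omitted it is derived as the union of all
        genes referenced by GPR rules; if given it must cover that union.
    compartments
        Mapping compartment code -> descriptive name.  If omitted it is
        derived from the metabolites' compartment codes.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str,
        genes: Iterable[str] | None = None,
        compartments: Mapping[str, str] | None = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.objective_id = objective_id
        referenced = frozenset().union(
            *(r.gpr.genes() for r in self.reactions), frozenset()
        )
        self.genes: set[str] = set(genes) if genes is not None else set(referenced)
        if compartments is not None:
            self.compartments: dict[str, str] = dict(compartments)
        else:
            self.compartments = {
                m.compartment: m.compartment for m in self.metabolites
            }
        self._validate(referenced)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- validation ---------------------------------------------------------

    def _validate(self, referenced_genes: frozenset[str]) -> None:
        problems: list[str] = []
        if not self.metabolites:
            problems.append("model has no metabolites")
        if not self.reactions:
            problems.append("model has no reactions")

        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            if any(not i for i in ids):
                problems.append(f"empty {label} id")
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    problems.append(f"duplicate {label} id {i!r}")
                seen.add(i)
        overlap = set(met_ids) & set(rxn_ids)
        if overlap:
            problems.append(
                f"reaction and metabolite id spaces overlap: {sorted(overlap)}"
            )

        met_set = set(met_ids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                problems.append(
                    f"reaction {r.id!r}: lower_bound {r.lower_bound} > "
                    f"upper_bound {r.upper_bound}"
                )
            if not any(c != 0 for c in r.stoichiometry.values()):
                problems.append(f"reaction {r.id!r}: no nonzero coefficient")
            missing = set(r.stoichiometry) - met_set
            if missing:
                problems.append(
                    f"reaction {r.id!r} references undeclared metabolites "
                    f"{sorted(missing)}"
                )
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                problems.append(
                    f"metabolite {m.id!r}: compartment {m.compartment!r} "
                    "not declared"
                )
        if self.objective_id not in set(rxn_ids):
            problems.append(f"objective {self.objective_id!r} is not a reaction")
        undeclared = referenced_genes - self.genes
        if undeclared:
            problems.append(
                f"GPR rules reference undeclared genes {sorted(undeclared)}"
            )
        if problems:
            raise ModelValidationError(problems)

    # -- lookups ------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self, metabolite_id: str) -> int:
        return self._met_index[metabolite_id]

    def reaction_index(self, reaction_id: str) -> int:
        return self._rxn_index[reaction_id]

    def get_metabolite(self, metabolite_id: str) -> Metabolite:
        return self.metabolites[self._met_index[metabolite_id]]

    def get_reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self._rxn_index[reaction_id]]

    def __contains__(self, any_id: str) -> bool:
        return any_id in self._rxn_index or any_id in self._met_index

    def __repr__(self) -> str:
        return (
            f"MetabolicModel({self.id!r}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes)"
        )

    # -- derived views ------------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Sparse S (metabolites x reactions); column j holds reaction j's
        coefficients."""
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                if coef != 0:
                    rows.append(self._met_index[met_id])
                    cols.append(j)
                    data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def reactions_for_gene(self, gene: str) -> set[str]:
        """Reactions whose GPR references ``gene`` (empty set if none)."""
        return {r.id for r in self.reactions if gene in r.gpr.genes()}

    def reactions_for_metabolite(self, metabolite_id: str) -> list[Reaction]:
        """Reactions with a nonzero coefficient for the metabolite."""
        if metabolite_id not in self._met_index:
            raise KeyError(f"unknown metabolite {metabolite_id!r}")
        return [
            r
            for r in self.reactions
            if r.stoichiometry.get(metabolite_id, 0.0) != 0.0
        ]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[_copy.copy(m) for m in self.metabolites],
            reactions=[
                Reaction(
                    id=r.id,
                    name=r.name,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    subsystem=r.subsystem,
                    gpr=r.gpr,
                )
                for r in self.reactions
            ],
            objective_id=self.objective_id,
            genes=set(self.genes),
            compartments=dict(self.compartments),
            id=self.id,
        )


# ---------------------------------------------------------------------------
# JSON dialect

_MET_FIELDS = {"id", "name", "compartment"}
_RXN_FIELDS = {
    "id",
    "name",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "subsystem",
    "gpr",
}
_TOP_FIELDS = {
    "schema",
    "id",
    "compartments",
    "metabolites",
    "reactions",
    "genes",
    "objective",
}


def _check_fields(obj: Mapping, allowed: set[str], required: set[str], what: str):
    missing = required - set(obj)
    extra = set(obj) - allowed
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing fields {sorted(missing)}")
        if extra:
            parts.append(f"unexpected fields {sorted(extra)}")
        raise JsonSchemaError(f"{what}: " + "; ".join(parts))


def _finite_bound(value: float, default: float) -> float:
    # JSON has no Infinity literal worth relying on; an explicit infinity
    # is stored as the conventional +/-1000 proxy.
    v = float(value)
    if math.isinf(v):
        return math.copysign(DEFAULT_BOUND, v)
    return v


def model_from_dict(doc: Mapping) -> MetabolicModel:
    """Build a validated model from a schema-1 dictionary."""
    if not isinstance(doc, Mapping):
        raise JsonSchemaError("top-level document must be an object")
    _check_fields(doc, _TOP_FIELDS, {"schema", "metabolites", "reactions", "objective"},
                  "model document")
    if doc["schema"] != JSON_SCHEMA_VERSION:
        raise JsonSchemaError(
            f"unsupported schema version {doc['schema']!r} "
            f"(expected {JSON_SCHEMA_VERSION})"
        )
    metabolites = []
    for entry in doc["metabolites"]:
        _check_fields(entry, _MET_FIELDS, {"id"}, f"metabolite {entry.get('id')!r}")
        metabolites.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", ""),
            )
        )
    reactions = []
    for entry in doc["reactions"]:
        _check_fields(
            entry, _RXN_FIELDS, {"id", "stoichiometry"}, f"reaction {entry.get('id')!r}"
        )
        reactions.append(
            Reaction(
                id=entry["id"],
                name=entry.get("name", ""),
                stoichiometry={
                    k: float(v) for k, v in entry["stoichiometry"].items()
                },
                lower_bound=_finite_bound(
                    entry.get("lower_bound", -DEFAULT_BOUND), -DEFAULT_BOUND
                ),
                upper_bound=_finite_bound(
                    entry.get("upper_bound", DEFAULT_BOUND), DEFAULT_BOUND
                ),
                subsystem=entry.get("subsystem", "unassigned"),
                gpr=parse_gpr(entry.get("gpr", "")),
            )
        )
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=doc["objective"],
        genes=doc.get("genes"),
        compartments=doc.get("compartments"),
        id=doc.get("id", "model"),
    )


def model_to_dict(model: MetabolicModel) -> dict:
    """Serialize a model to the schema-1 dictionary form."""
    return {
        "schema": JSON_SCHEMA_VERSION,
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "subsystem": r.subsystem,
                "gpr": r.gpr.source_text,
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_id,
    }


def read_json_model(path: str | Path) -> MetabolicModel:
    """Read a model from the package JSON dialect.

    Raises :class:`JsonSchemaError` on schema violations and
    :class:`ModelValidationError` on structural invariant violations.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise JsonSchemaError(f"not valid JSON: {exc}") from exc
    return model_from_dict(doc)


def write_json_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the package JSON dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")
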