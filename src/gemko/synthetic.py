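"""Synthetic metabolic networks with analytic ground truth.

The generator emulates, at toy scale, the network situation of a
lysosomal-enzyme deficiency in a genome-scale model: a growth (biomass)
objective fed by a limited shared resource, and a gene-gated multi-step
catabolic branch (a glycosaminoglycan-degradation mimic) that competes
for the same resource.  Deleting the focal gene blocks the branch while
leaving growth untouched — the branch is purely catabolic — and every
chain intermediate upstream of the block loses all of its consumers.

Topology (``k`` chain steps, ``n = k - 1`` of them internal when every
step is gated; in general ``n_intermediates`` internal metabolites and
``n_intermediates + 1`` steps of which the first ``chain_length`` are
gated by the focal gene)::

    EX_res  <->  res_e  ->  res_c  ->  BIOMASS   (yield per unit growth)
    SRC_gag  ->  gag_l  ->  im_1  ->  ...  ->  im_n  ->  (degraded)
                  |                                   ^ each gated step also
                  +-> BY_gag (optional bypass)          consumes res_c

The gated steps together consume ``degradation_cost`` units of resource
per unit of branch flux, so with budget ``B``, biomass yield ``y`` and an
optimality fraction ``f`` the analytic ground truth is:

* wild-type biomass optimum ``B / y``;
* branch flux capacity ``B (1 - f) / degradation_cost``;
* knockout biomass change exactly zero.

The random seed shuffles identifier order and draws decoy-reaction
bounds only; the topology that defines the ground truth never depends
on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gpr import parse_gpr
from .model import (
    Metabolite,
    MetabolicModel,
    Reaction,
    model_from_dict,
    model_to_dict,
    write_json_model,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "write_fixture",
    "read_ground_truth",
    "FOCAL_GENE",
]

FOCAL_GENE = "G_IDS"

TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated network.

    chain_length
        Number of gene-gated degradation steps (>= 1).
    n_intermediates
        Metabolites strictly inside the catabolic chain; the chain has
        ``n_intermediates + 1`` steps in total and ``chain_length`` of
        them (the upstream ones) are gated, so ``chain_length <=
        n_intermediates + 1``.
    resource_budget
        Uptake ceiling of the shared resource (flux units).
    biomass_yield
        Resource units consumed per unit of biomass flux.
    degradation_cost
        Resource units consumed per unit of branch flux (split evenly
        over the gated steps).
    bypass
        Whether the polymer has a non-gated alternative consumer, which
        keeps its consumption alive in the knockout.
    n_decoys
        Independent uptake/use reaction pairs padding the network; never
        affected by the knockout.
    seed
        Controls identifier ordering and decoy bounds only.
    """

    chain_length: int = 3
    n_intermediates: int = 4
    resource_budget: float = 10.0
    biomass_yield: float = 1.0
    degradation_cost: float = 1.0
    bypass: bool = False
    n_decoys: int = 2
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.chain_length < 1:
            problems.append("chain_length must be >= 1")
        if self.n_intermediates < 0:
            problems.append("n_intermediates must be >= 0")
        if self.chain_length > self.n_intermediates + 1:
            problems.append(
                "chain_length may not exceed n_intermediates + 1 "
                "(the chain has n_intermediates + 1 steps)"
            )
        for name in ("resource_budget", "biomass_yield", "degradation_cost"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.n_decoys < 0:
            problems.append("n_decoys must be >= 0")
        if problems:
            raise ValueError(
                "infeasible synthetic spec:\n  - " + "\n  - ".join(problems)
            )


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable expectations for a generated network."""

    gene: str
    gated_reactions: frozenset[str]
    chain_reactions: tuple[str, ...]  # upstream -> downstream order
    expected_affected: frozenset[str]
    expected_accumulating: frozenset[str]
    expected_biomass: float
    resource_budget: float
    degradation_cost: float

    def expected_branch_capacity(self, fraction: float) -> float:
        """Analytic branch flux ceiling at an optimality fraction."""
        return self.resource_budget * (1.0 - fraction) / self.degradation_cost

    def max_detectable_fraction(self, threshold: float) -> float:
        """Largest fraction at which the branch capacity (hence Δrange of
        every blocked chain reaction) still exceeds the significance
        threshold."""
        return 1.0 - threshold * self.degradation_cost / self.resource_budget

    def to_dict(self) -> dict:
        return {
            "schema": TRUTH_SCHEMA_VERSION,
            "gene": self.gene,
            "gated_reactions": sorted(self.gated_reactions),
            "chain_reactions": list(self.chain_reactions),
            "expected_affected": sorted(self.expected_affected),
            "expected_accumulating": sorted(self.expected_accumulating),
            "expected_biomass": self.expected_biomass,
            "resource_budget": self.resource_budget,
            "degradation_cost": self.degradation_cost,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "GroundTruth":
        if doc.get("schema") != TRUTH_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported ground-truth schema {doc.get('schema')!r}"
            )
        return cls(
            gene=doc["gene"],
            gated_reactions=frozenset(doc["gated_reactions"]),
            chain_reactions=tuple(doc["chain_reactions"]),
            expected_affected=frozenset(doc["expected_affected"]),
            expected_accumulating=frozenset(doc["expected_accumulating"]),
            expected_biomass=float(doc["expected_biomass"]),
            resource_budget=float(doc["resource_budget"]),
            degradation_cost=float(doc["degradation_cost"]),
        )


def generate(spec: SyntheticSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Build a model and its ground truth from a spec.

    The wild-type biomass optimum is ``resource_budget / biomass_yield``
    by construction; the knockout leaves it unchanged because the gated
    branch only ever competes for — never supplies — the resource.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    compartments = {"e": "extracellular", "c": "cytosol", "l": "lysosome"}
    metabolites = [
        Metabolite("res_e", "shared resource (extracellular)", "e"),
        Metabolite("res_c", "shared resource (cytosol)", "c"),
        Metabolite("gag_l", "sulfated polymer (lysosome)", "l"),
    ]
    intermediates = [
        Metabolite(f"im_{i + 1}", f"degradation intermediate {i + 1}", "l")
        for i in range(spec.n_intermediates)
    ]
    metabolites += intermediates

    n_steps = spec.n_intermediates + 1
    cost_share = spec.degradation_cost / spec.chain_length

    reactions = [
        Reaction(
            id="EX_res",
            name="resource exchange",
            stoichiometry={"res_e": -1.0},
            lower_bound=-spec.resource_budget,
            upper_bound=0.0,
            subsystem="exchange/demand",
        ),
        Reaction(
            id="T_res",
            name="resource import",
            stoichiometry={"res_e": -1.0, "res_c": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="core",
        ),
        Reaction(
            id="BIOMASS",
            name="growth objective",
            stoichiometry={"res_c": -spec.biomass_yield},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="core",
        ),
        Reaction(
            id="SRC_gag",
            name="polymer influx",
            stoichiometry={"gag_l": 1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="exchange/demand",
        ),
    ]

    chain_mets = ["gag_l"] + [m.id for m in intermediates]
    chain_ids: list[str] = []
    for i in range(n_steps):
        gated = i < spec.chain_length
        stoich: dict[str, float] = {chain_mets[i]: -1.0}
        if i + 1 < len(chain_mets):
            stoich[chain_mets[i + 1]] = 1.0
        if gated:
            stoich["res_c"] = stoich.get("res_c", 0.0) - cost_share
        rid = f"STEP_{i + 1}"
        chain_ids.append(rid)
        reactions.append(
            Reaction(
                id=rid,
                name=f"degradation step {i + 1}"
                + (" (gene-gated)" if gated else ""),
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=1000.0,
                subsystem="degradation",
                gpr=parse_gpr(FOCAL_GENE) if gated else parse_gpr(""),
            )
        )

    if spec.bypass:
        reactions.append(
            Reaction(
                id="BY_gag",
                name="polymer bypass consumer",
                stoichiometry={"gag_l": -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                subsystem="exchange/demand",
            )
        )

    for i in range(spec.n_decoys):
        uptake = float(rng.integers(1, 21))
        met_e = Metabolite(f"dec_{i + 1}_e", f"decoy nutrient {i + 1}", "e")
        met_c = Metabolite(f"dec_{i + 1}_c", f"decoy nutrient {i + 1}", "c")
        metabolites += [met_e, met_c]
        reactions += [
            Reaction(
                id=f"EX_dec_{i + 1}",
                stoichiometry={met_e.id: -1.0},
                lower_bound=-uptake,
                upper_bound=0.0,
                subsystem="exchange/demand",
            ),
            Reaction(
                id=f"T_dec_{i + 1}",
                stoichiometry={met_e.id: -1.0, met_c.id: 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                subsystem="core",
            ),
            Reaction(
                id=f"DM_dec_{i + 1}",
                stoichiometry={met_c.id: -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                subsystem="core",
            ),
        ]

    # the seed shuffles presentation order only
    rng.shuffle(metabolites)
    rng.shuffle(reactions)

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id="BIOMASS",
        genes={FOCAL_GENE},
        compartments=compartments,
        id=f"synthetic_seed{spec.seed}",
    )

    gated = frozenset(chain_ids[: spec.chain_length])
    affected = set(chain_ids)
    accumulating = {m.id for m in intermediates}
    if not spec.bypass:
        # without the bypass, blocking the chain also silences the polymer
        # source and strands the polymer itself
        affected.add("SRC_gag")
        accumulating.add("gag_l")
    truth = GroundTruth(
        gene=FOCAL_GENE,
        gated_reactions=gated,
        chain_reactions=tuple(chain_ids),
        expected_affected=frozenset(affected),
        expected_accumulating=frozenset(accumulating),
        expected_biomass=spec.resource_budget / spec.biomass_yield,
        resource_budget=spec.resource_budget,
        degradation_cost=spec.degradation_cost,
    )
    return model, truth


def write_fixture(
    model: MetabolicModel, truth: GroundTruth, path: str | Path
) -> tuple[Path, Path]:
    """Write the model JSON and a ``.truth.json`` sidecar next to it."""
    path = Path(path)
    write_json_model(model, path)
    sidecar = path.with_suffix(".truth.json")
    with open(sidecar, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path, sidecar


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupted ground-truth sidecar: {exc}") from exc
    return GroundTruth.from_dict(doc)
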