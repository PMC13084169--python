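"""Gene-knockout simulation and the flux-range change (Δrange) statistic.

A single-gene knockout is simulated through the GPR rules: every reaction
whose rule evaluates to False with the gene deleted loses its catalysing
enzyme, so its flux bounds are pinned to zero.  Wild-type (WT) and
knockout (KO) models are then compared by FVA at a common optimality
fraction, and each reaction's perturbation is quantified as

    delta_range = |max_KO - max_WT| + |min_KO - min_WT|

the summed absolute displacement of its flux-range endpoints.  Absolute
values are taken for both terms so that opposite-signed endpoint shifts
cannot cancel and mask a genuine perturbation; the statistic is therefore
symmetric in which model is called WT and which KO.

Reactions with ``delta_range`` above a significance threshold (default
1.0, separating the bimodal genuine-change/solver-jitter distribution)
are re-solved at a tightened solver tolerance; if the recomputed change
collapses below the threshold the original value was numerical noise,
otherwise the reaction is genuinely affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .lp import FEASIBILITY_TOLERANCE, FluxRange, fba, fva
from .gpr import rule_active
from .model import MetabolicModel

__all__ = [
    "PerturbationRecord",
    "KnockoutResult",
    "apply_knockout",
    "delta_range",
    "build_records",
    "classify_records",
    "simulate_knockout",
    "subsystem_distribution",
    "capacity_loss_percent",
    "affected_fraction_percent",
    "reachable_reactions",
    "UNCHANGED",
    "AFFECTED",
    "NUMERICAL_NOISE",
]

logger = logging.getLogger(__name__)

UNCHANGED = "unchanged"
AFFECTED = "affected"
NUMERICAL_NOISE = "numerical_noise"

#: Default Δrange significance threshold.
SIGNIFICANCE_THRESHOLD = 1.0

#: Tightened solver tolerance used when retesting putative noise.
NOISE_RETEST_TOLERANCE = 1e-10


@dataclass
class PerturbationRecord:
    """Per-reaction WT/KO flux ranges, Δrange and its classification."""

    reaction_id: str
    wt_range: FluxRange
    ko_range: FluxRange
    delta_range: float
    classification: str
    subsystem: str


@dataclass
class KnockoutResult:
    """Full outcome of one single-gene knockout comparison."""

    gene: str
    disabled_reactions: frozenset[str]
    wt_biomass: float
    ko_biomass: float
    records: list[PerturbationRecord]
    fraction: float
    threshold: float = SIGNIFICANCE_THRESHOLD

    @property
    def relative_growth_change(self) -> float:
        """(KO - WT) / WT biomass; 0 growth impact gives 0."""
        if self.wt_biomass == 0:
            return 0.0
        return (self.ko_biomass - self.wt_biomass) / self.wt_biomass

    @property
    def affected(self) -> list[PerturbationRecord]:
        return [r for r in self.records if r.classification == AFFECTED]

    @property
    def affected_reaction_ids(self) -> frozenset[str]:
        return frozenset(r.reaction_id for r in self.affected)

    def counts(self) -> dict[str, int]:
        out = {UNCHANGED: 0, AFFECTED: 0, NUMERICAL_NOISE: 0}
        for r in self.records:
            out[r.classification] += 1
        return out


def apply_knockout(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Return a copy of the model with the gene's reactions disabled.

    Every reaction whose GPR evaluates to False under deletion of ``gene``
    gets ``lower_bound = upper_bound = 0``; everything else is untouched.
    The input model is not modified.  A gene not referenced by any GPR
    yields a warning and an unchanged copy (reactions without a GPR are
    never deletable).
    """
    ko = model.copy()
    if gene not in model.genes and not model.reactions_for_gene(gene):
        logger.warning("gene %s is not referenced by any GPR rule", gene)
        return ko
    deleted = {gene}
    for rxn in ko.reactions:
        if not rxn.gpr.is_empty and not rule_active(rxn.gpr, deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return ko


def disabled_by_knockout(model: MetabolicModel, gene: str) -> frozenset[str]:
    """Reactions whose GPR goes inactive when ``gene`` is deleted."""
    return frozenset(
        r.id
        for r in model.reactions
        if not r.gpr.is_empty and not rule_active(r.gpr, {gene})
    )


def delta_range(wt: FluxRange, ko: FluxRange) -> float:
    """Summed absolute endpoint displacement between two flux ranges.

    Requires both ranges to describe the same reaction at the same
    optimality fraction.
    """
    if wt.reaction_id != ko.reaction_id:
        raise ValueError(
            f"mismatched reactions: {wt.reaction_id!r} vs {ko.reaction_id!r}"
        )
    if wt.fraction != ko.fraction:
        raise ValueError(
            f"mismatched optimality fractions: {wt.fraction} vs {ko.fraction}"
        )
    return abs(ko.max_flux - wt.max_flux) + abs(ko.min_flux - wt.min_flux)


def build_records(
    model: MetabolicModel,
    wt_ranges: Mapping[str, FluxRange],
    ko_ranges: Mapping[str, FluxRange],
) -> list[PerturbationRecord]:
    """Pair WT/KO ranges into unclassified records (all marked unchanged)."""
    records = []
    for rid in wt_ranges:
        if rid not in ko_ranges:
            continue
        records.append(
            PerturbationRecord(
                reaction_id=rid,
                wt_range=wt_ranges[rid],
                ko_range=ko_ranges[rid],
                delta_range=delta_range(wt_ranges[rid], ko_ranges[rid]),
                classification=UNCHANGED,
                subsystem=model.get_reaction(rid).subsystem,
            )
        )
    return records


def classify_records(
    records: Iterable[PerturbationRecord],
    threshold: float,
    wt_model: MetabolicModel,
    ko_model: MetabolicModel,
    *,
    retest_tolerance: float = NOISE_RETEST_TOLERANCE,
) -> list[PerturbationRecord]:
    """Split records into unchanged / affected / numerical noise.

    Records at or below the threshold are unchanged.  Records above it are
    re-evaluated with the solver tolerance tightened to
    ``retest_tolerance``; if the recomputed Δrange falls to or below the
    threshold the original excess was solver jitter and the record is
    labelled numerical noise, otherwise it is affected.  The originally
    computed Δrange is kept on the record either way.
    """
    if threshold <= 0:
        raise ValueError(f"significance threshold must be > 0, got {threshold}")
    records = list(records)
    suspect = [r for r in records if r.delta_range > threshold]
    if suspect:
        suspect_ids = [r.reaction_id for r in suspect]
        fraction = suspect[0].wt_range.fraction
        wt_retest = fva(
            wt_model, fraction, suspect_ids, tolerance=retest_tolerance
        )
        ko_retest = fva(
            ko_model, fraction, suspect_ids, tolerance=retest_tolerance
        )
        for rec in suspect:
            redo = delta_range(
                wt_retest[rec.reaction_id], ko_retest[rec.reaction_id]
            )
            rec.classification = (
                NUMERICAL_NOISE if redo <= threshold else AFFECTED
            )
    for rec in records:
        if rec.delta_range <= threshold:
            rec.classification = UNCHANGED
    return records


def simulate_knockout(
    model: MetabolicModel,
    gene: str,
    fraction: float = 0.9,
    reactions: Iterable[str] | None = None,
    *,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    tolerance: float = FEASIBILITY_TOLERANCE,
    retest_tolerance: float = NOISE_RETEST_TOLERANCE,
) -> KnockoutResult:
    """Run the full WT-vs-KO comparison for one gene.

    Steps: apply the knockout through the GPRs, solve FBA for both models,
    run FVA on both at the given optimality fraction (each against its own
    optimum), compute per-reaction Δrange and classify.  ``reactions``
    restricts the FVA scope; default is genome-wide.
    """
    ko_model = apply_knockout(model, gene)
    wt_sol = fba(model, tolerance=tolerance)
    ko_sol = fba(ko_model, tolerance=tolerance)
    if not wt_sol.optimal:
        raise RuntimeError(f"wild-type FBA is {wt_sol.status}")
    if not ko_sol.optimal:
        raise RuntimeError(f"knockout FBA is {ko_sol.status}")
    wt_ranges = fva(model, fraction, reactions, tolerance=tolerance)
    ko_ranges = fva(ko_model, fraction, reactions, tolerance=tolerance)
    records = build_records(model, wt_ranges, ko_ranges)
    records = classify_records(
        records, threshold, model, ko_model, retest_tolerance=retest_tolerance
    )
    return KnockoutResult(
        gene=gene,
        disabled_reactions=disabled_by_knockout(model, gene),
        wt_biomass=wt_sol.objective_value,
        ko_biomass=ko_sol.objective_value,
        records=records,
        fraction=fraction,
        threshold=threshold,
    )


def subsystem_distribution(
    records: Iterable[PerturbationRecord],
) -> dict[str, int]:
    """Affected-reaction counts per subsystem, descending by count."""
    counts: dict[str, int] = {}
    for rec in records:
        if rec.classification == AFFECTED:
            counts[rec.subsystem] = counts.get(rec.subsystem, 0) + 1
    return dict(
        sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    )


def capacity_loss_percent(wt: FluxRange, ko: FluxRange) -> float:
    """Percentage of WT maximum flux capacity lost in the knockout.

    ``100 * (max_WT - max_KO) / max_WT``; a reaction whose range collapses
    from [0, 140] to [0, 0] has lost 100% of its capacity.
    """
    if wt.reaction_id != ko.reaction_id:
        raise ValueError(
            f"mismatched reactions: {wt.reaction_id!r} vs {ko.reaction_id!r}"
        )
    if wt.max_flux == 0:
        return 0.0
    return 100.0 * (wt.max_flux - ko.max_flux) / wt.max_flux


def affected_fraction_percent(n_affected: int, n_reactions: int) -> float:
    """Share of the network significantly affected, as a percentage
    rounded to two decimals (40 of 12,971 reactions -> 0.31)."""
    if n_reactions <= 0:
        raise ValueError("n_reactions must be positive")
    return round(100.0 * n_affected / n_reactions, 2)


def reachable_reactions(
    model: MetabolicModel,
    seeds: Iterable[str],
    barrier_metabolites: Iterable[str] = (),
) -> frozenset[str]:
    """Reactions in the metabolite-reaction graph component reachable from
    ``seeds`` without traversing any barrier metabolite.

    Used to check the locality of a perturbation: on a network where a
    knocked-out branch touches the rest of the system only through a
    shared resource metabolite, the affected set must stay inside the
    component reachable from the disabled reactions with that resource
    removed.
    """
    g = nx.Graph()
    barriers = set(barrier_metabolites)
    for r in model.reactions:
        g.add_node(("r", r.id))
        for met_id in r.stoichiometry:
            if met_id in barriers:
                continue
            g.add_edge(("r", r.id), ("m", met_id))
    out: set[str] = set()
    for seed in seeds:
        node = ("r", seed)
        if node in g:
            out.update(
                rid for kind, rid in nx.node_connected_component(g, node)
                if kind == "r"
            )
    return frozenset(out)
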