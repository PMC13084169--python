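"""Reporter metabolites: species predicted to accumulate after a knockout.

At steady state a constraint-based model carries no concentrations, but a
qualitative accumulation prediction follows from flux ranges: if every
reaction able to *consume* a metabolite was active in the wild type and is
fully blocked in the knockout, the metabolite's degradation routes are all
gone while its production routes may persist, so it is flagged as
potentially accumulating.  For a lysosomal-enzyme deficiency this is the
network analogue of storage-disorder substrate build-up.

"Able to consume" is decided on FVA ranges, not nominal directionality:
a reaction consumes the metabolite if its stoichiometric coefficient is
negative and the range admits forward flux (max > tol), or the
coefficient is positive and the range admits reverse flux (min < -tol).
"Blocked" means the entire knockout range lies within +/- tol of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .lp import FluxRange
from .model import MetabolicModel

__all__ = [
    "BLOCKED_TOLERANCE",
    "AccumulationCandidate",
    "AccumulationReport",
    "consuming_reactions",
    "find_accumulating",
    "compartment_summary",
]

#: Flux magnitude below which a reaction is considered unable to carry flux.
BLOCKED_TOLERANCE = 1e-6


@dataclass(frozen=True)
class AccumulationCandidate:
    metabolite_id: str
    compartment: str
    consuming_reactions: tuple[str, ...]
    category: str


@dataclass
class AccumulationReport:
    """Metabolites whose every consumer is WT-active and KO-blocked."""

    gene: str
    candidates: list[AccumulationCandidate]
    universe_size: int  # number of metabolites scanned

    @property
    def count(self) -> int:
        return len(self.candidates)

    def by_category(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.candidates:
            counts[c.category] = counts.get(c.category, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))

    def by_compartment(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.candidates:
            counts[c.compartment] = counts.get(c.compartment, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def consuming_reactions(
    model: MetabolicModel,
    metabolite: str,
    ranges: Mapping[str, FluxRange],
    tol: float = BLOCKED_TOLERANCE,
) -> set[str]:
    """Reactions able to consume the metabolite under the given flux ranges.

    Raises ``KeyError`` for an unknown metabolite.  Reactions touching the
    metabolite but absent from ``ranges`` are treated as not evaluated and
    ignored, so callers should pass ranges covering all touching reactions.
    """
    out: set[str] = set()
    for rxn in model.reactions_for_metabolite(metabolite):
        rng = ranges.get(rxn.id)
        if rng is None:
            continue
        coef = rxn.stoichiometry[metabolite]
        if coef < 0 and rng.max_flux > tol:
            out.add(rxn.id)
        elif coef > 0 and rng.min_flux < -tol:
            out.add(rxn.id)
    return out


def _majority_category(
    model: MetabolicModel, consumer_ids: Sequence[str]
) -> str:
    """Majority subsystem of the consuming reactions; ties -> 'other'."""
    counts: dict[str, int] = {}
    for rid in consumer_ids:
        sub = model.get_reaction(rid).subsystem
        counts[sub] = counts.get(sub, 0) + 1
    best = max(counts.values())
    winners = [s for s, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else "other"


def find_accumulating(
    model: MetabolicModel,
    wt_ranges: Mapping[str, FluxRange],
    ko_ranges: Mapping[str, FluxRange],
    metabolites: Iterable[str] | None = None,
    *,
    gene: str = "",
    tol: float = BLOCKED_TOLERANCE,
) -> AccumulationReport:
    """Flag metabolites whose consumption is WT-active but KO-blocked.

    A metabolite is a candidate iff its consuming-reaction set under the
    wild-type ranges is non-empty and every one of those consumers has a
    knockout range entirely within ``[-tol, +tol]``.  Each candidate is
    labelled with its compartment and with a pathway category derived from
    the majority subsystem of its consuming reactions.

    ``metabolites`` restricts the scanned universe (e.g. to participants
    of knockout-affected reactions); by default every metabolite touched
    by a reaction present in both range sets is scanned.
    """
    if metabolites is None:
        covered = set(wt_ranges) & set(ko_ranges)
        universe: list[str] = [
            m.id
            for m in model.metabolites
            if any(
                r.id in covered for r in model.reactions_for_metabolite(m.id)
            )
        ]
    else:
        universe = list(dict.fromkeys(metabolites))

    candidates: list[AccumulationCandidate] = []
    for met_id in universe:
        consumers = consuming_reactions(model, met_id, wt_ranges, tol)
        if not consumers:
            continue
        if any(rid not in ko_ranges for rid in consumers):
            continue
        if all(ko_ranges[rid].blocked(tol) for rid in consumers):
            ordered = tuple(sorted(consumers))
            candidates.append(
                AccumulationCandidate(
                    metabolite_id=met_id,
                    compartment=model.get_metabolite(met_id).compartment,
                    consuming_reactions=ordered,
                    category=_majority_category(model, ordered),
                )
            )
    return AccumulationReport(
        gene=gene, candidates=candidates, universe_size=len(universe)
    )


def compartment_summary(
    report: AccumulationReport,
) -> dict[str, tuple[int, int]]:
    """Per-compartment candidate counts with integer-rounded percentages.

    32 lysosomal candidates out of 34 report as ``(32, 94)``.  Counts sum
    to the candidate total; an empty report gives an empty map.
    """
    total = report.count
    if total == 0:
        return {}
    return {
        comp: (n, round(100.0 * n / total))
        for comp, n in report.by_compartment().items()
    }
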