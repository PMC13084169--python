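"""Optimality-threshold sensitivity: capacity curves and robustness sweeps.

FVA results depend on how much of the optimal growth must be maintained.
Two questions are answered here:

* How does a reaction's maximum attainable flux grow as the growth
  constraint is relaxed?  (:func:`capacity_curve` — at 100% optimality a
  purely catabolic branch typically has zero capacity, and capacity rises
  monotonically as the optimality fraction drops, reflecting a trade-off
  against growth for shared resources.)
* Is the set of knockout-affected reactions stable across optimality
  fractions?  (:func:`threshold_robustness` — re-runs the whole knockout
  pipeline per fraction and reports whether the affected sets are
  identical, with symmetric differences when they are not.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lp import FEASIBILITY_TOLERANCE, fva
from .model import MetabolicModel
from .perturbation import (
    SIGNIFICANCE_THRESHOLD,
    KnockoutResult,
    simulate_knockout,
    subsystem_distribution,
)

__all__ = [
    "CapacityCurve",
    "FractionSummary",
    "RobustnessResult",
    "capacity_curve",
    "threshold_robustness",
    "DEFAULT_FRACTIONS",
]

#: Default sweep grid of optimality fractions.
DEFAULT_FRACTIONS = (1.0, 0.9, 0.75, 0.5)

_MONOTONE_TOL = 1e-6


@dataclass(frozen=True)
class CapacityCurve:
    """Maximum attainable flux of one reaction versus optimality fraction.

    Points are sorted by strictly increasing fraction; construction fails
    if max capacity is not non-increasing in the fraction (the feasible
    regions are nested, so a violation indicates a solver failure).
    """

    reaction_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        fracs = [f for f, _ in self.points]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("fractions must be strictly increasing")
        caps = [c for _, c in self.points]
        for a, b in zip(caps, caps[1:]):
            if b > a + _MONOTONE_TOL:
                raise ValueError(
                    f"capacity not non-increasing for {self.reaction_id}: "
                    f"{a} -> {b}"
                )

    def capacity_at(self, fraction: float) -> float:
        for f, c in self.points:
            if f == fraction:
                return c
        raise KeyError(f"fraction {fraction} not in curve")

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(f for f, _ in self.points)


def capacity_curve(
    model: MetabolicModel,
    reaction: str,
    fractions: Sequence[float],
    *,
    tolerance: float = FEASIBILITY_TOLERANCE,
) -> CapacityCurve:
    """FVA maximum of one reaction at each requested optimality fraction."""
    pts = []
    for f in sorted(set(fractions)):
        ranges = fva(model, f, [reaction], tolerance=tolerance)
        pts.append((f, ranges[reaction].max_flux))
    return CapacityCurve(reaction_id=reaction, points=tuple(pts))


@dataclass
class FractionSummary:
    """Knockout outcome at one optimality fraction."""

    fraction: float
    affected_count: int
    subsystems: dict[str, int]
    affected_set: frozenset[str]
    result: KnockoutResult


@dataclass
class RobustnessResult:
    """Affected-set stability of a knockout across optimality fractions."""

    gene: str
    per_fraction: dict[float, FractionSummary]
    sets_identical: bool
    set_differences: dict[tuple[float, float], frozenset[str]] = field(
        default_factory=dict
    )

    def counts(self) -> dict[float, int]:
        return {f: s.affected_count for f, s in self.per_fraction.items()}


def threshold_robustness(
    model: MetabolicModel,
    gene: str,
    fractions: Sequence[float],
    threshold: float = SIGNIFICANCE_THRESHOLD,
    *,
    tolerance: float = FEASIBILITY_TOLERANCE,
) -> RobustnessResult:
    """Re-run the knockout pipeline at each fraction and compare outcomes.

    The headline indicator is whether the affected-reaction sets are
    *identical* across fractions (not merely equal in size); pairwise
    symmetric differences are reported when they are not.
    """
    per_fraction: dict[float, FractionSummary] = {}
    for f in fractions:
        result = simulate_knockout(
            model, gene, f, threshold=threshold, tolerance=tolerance
        )
        per_fraction[f] = FractionSummary(
            fraction=f,
            affected_count=len(result.affected),
            subsystems=subsystem_distribution(result.records),
            affected_set=result.affected_reaction_ids,
            result=result,
        )
    fracs = list(per_fraction)
    sets_identical = True
    differences: dict[tuple[float, float], frozenset[str]] = {}
    for a, b in zip(fracs, fracs[1:]):
        diff = per_fraction[a].affected_set ^ per_fraction[b].affected_set
        if diff:
            sets_identical = False
            differences[(a, b)] = frozenset(diff)
    return RobustnessResult(
        gene=gene,
        per_fraction=per_fraction,
        sets_identical=sets_identical,
        set_differences=differences,
    )
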