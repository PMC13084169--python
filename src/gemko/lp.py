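"""Flux balance analysis (FBA) and flux variability analysis (FVA).

Both are linear programs over the flux vector ``v`` of a stoichiometric
network at steady state:

* FBA maximizes the objective (biomass) flux subject to ``S v = 0`` and
  the flux bounds ``lb <= v <= ub``, giving the optimum Z_opt.
* FVA then, for each reaction r, minimizes and maximizes ``v_r`` subject
  to the same constraints plus an optimality floor on the objective,
  ``v_obj >= fraction * Z_opt``.  The resulting [min, max] interval is the
  reaction's attainable flux range across all near-optimal states, which
  characterises alternative optima that a single FBA solution hides.

The solver is HiGHS via :func:`scipy.optimize.linprog`, which is
deterministic: constraint ordering is fixed by the model, nothing is
randomized, and repeated runs give identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "FluxRange",
    "FvaError",
    "fba",
    "fva",
    "FEASIBILITY_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: Default primal/dual feasibility tolerance handed to the solver.
FEASIBILITY_TOLERANCE = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


class FvaError(RuntimeError):
    """The base model for an FVA run is infeasible or unbounded."""


@dataclass
class FluxSolution:
    """Outcome of a single FBA solve."""

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FluxRange:
    """Attainable [min, max] flux of one reaction at an optimality fraction."""

    reaction_id: str
    min_flux: float
    max_flux: float
    fraction: float

    @property
    def width(self) -> float:
        return self.max_flux - self.min_flux

    def blocked(self, tol: float = 1e-6) -> bool:
        """Whole range within +/- tol of zero: the reaction can carry no flux."""
        return abs(self.min_flux) <= tol and abs(self.max_flux) <= tol


def _solver_options(tolerance: float) -> dict:
    return {
        "presolve": True,
        "primal_feasibility_tolerance": tolerance,
        "dual_feasibility_tolerance": max(tolerance, 1e-11),
    }


def fba(
    model: MetabolicModel, *, tolerance: float = FEASIBILITY_TOLERANCE
) -> FluxSolution:
    """Maximize the objective flux subject to ``S v = 0`` and the bounds.

    Returns a :class:`FluxSolution` whose ``status`` faithfully reports
    infeasibility or unboundedness; fluxes are only populated when optimal.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index(model.objective_id)] = -1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_solver_options(tolerance),
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status)
    fluxes = dict(zip(model.reaction_ids, map(float, res.x)))
    return FluxSolution(
        status="optimal",
        objective_value=float(res.x[model.reaction_index(model.objective_id)]),
        fluxes=fluxes,
    )


def fva(
    model: MetabolicModel,
    fraction: float = 1.0,
    reactions: Iterable[str] | None = None,
    *,
    tolerance: float = FEASIBILITY_TOLERANCE,
) -> dict[str, FluxRange]:
    """Per-reaction flux ranges while holding near-optimal growth.

    For each requested reaction (default: all), solves two LPs: minimize
    and maximize its flux subject to steady state, the bounds, and
    ``v_obj >= fraction * Z_opt`` where Z_opt is the model's own FBA
    optimum.  ``fraction`` is the decimal form of the printed percentage
    (90% optimality -> 0.9).

    A per-reaction LP failure is logged and that endpoint reported as NaN;
    the run continues.  An infeasible or unbounded base model raises
    :class:`FvaError`.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    base = fba(model, tolerance=tolerance)
    if not base.optimal:
        raise FvaError(f"base model is {base.status}; cannot run FVA")
    z_opt = base.objective_value
    if z_opt < -tolerance:
        raise FvaError(f"negative objective optimum {z_opt}; cannot run FVA")

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    obj_idx = model.reaction_index(model.objective_id)
    bounds = np.column_stack([lb, ub])
    # optimality floor: v_obj >= fraction * Z_opt  <=>  -v_obj <= -fraction*Z
    a_ub = sparse.csr_matrix(
        ([-1.0], ([0], [obj_idx])), shape=(1, n)
    )
    b_ub = np.array([-fraction * z_opt])
    b_eq = np.zeros(S.shape[0])
    options = _solver_options(tolerance)

    targets = list(reactions) if reactions is not None else model.reaction_ids
    ranges: dict[str, FluxRange] = {}
    for rid in targets:
        j = model.reaction_index(rid)
        c = np.zeros(n)
        endpoints = []
        for sign in (1.0, -1.0):  # minimize, then maximize
            c[j] = sign
            res = linprog(
                c,
                A_ub=a_ub,
                b_ub=b_ub,
                A_eq=S,
                b_eq=b_eq,
                bounds=bounds,
                method="highs",
                options=options,
            )
            if res.status != 0:
                logger.warning(
                    "FVA LP for reaction %s (%s) ended with status %s",
                    rid,
                    "min" if sign > 0 else "max",
                    _STATUS.get(res.status, "failed"),
                )
                endpoints.append(float("nan"))
            else:
                endpoints.append(float(res.x[j]))
            c[j] = 0.0
        vmin, vmax = (v + 0.0 for v in endpoints)  # normalize -0.0
        if vmin == vmin and vmax == vmax and vmin > vmax:
            # numerically crossed endpoints; collapse to midpoint ordering
            vmin, vmax = min(vmin, vmax), max(vmin, vmax)
        ranges[rid] = FluxRange(
            reaction_id=rid, min_flux=vmin, max_flux=vmax, fraction=fraction
        )
    return ranges
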