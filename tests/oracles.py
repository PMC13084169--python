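"""Independent brute-force oracles used to cross-check the LP engine.

The flux polytope {v : S v = 0, lb <= v <= ub, (optionally) c.v >= r} is
bounded (all bounds finite), so every LP optimum is attained at a vertex.
A vertex is the unique solution of the equalities plus a subset of active
inequality constraints with total rank n.  For networks with <= ~6
reactions exhaustive enumeration of those subsets is cheap and entirely
independent of any LP solver.
"""

import itertools

import numpy as np


def enumerate_vertices(S, lb, ub, floor=None, tol=1e-7):
    """All vertices of the flux polytope.

    ``floor`` is an optional pair (c, rhs) adding the half-space
    c.v >= rhs (the FVA optimality floor).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = S.shape[1]
    ineqs = []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        ineqs.append((e, lb[i]))
        ineqs.append((e, ub[i]))
    if floor is not None:
        c, rhs = floor
        ineqs.append((np.asarray(c, dtype=float), rhs))

    def feasible(v):
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            return False
        if np.max(np.abs(S @ v), initial=0.0) > 1e-8:
            return False
        if floor is not None and ineqs[-1][0] @ v < ineqs[-1][1] - tol:
            return False
        return True

    vertices = []
    rank_s = np.linalg.matrix_rank(S) if S.size else 0
    need = n - rank_s
    for combo in itertools.combinations(range(len(ineqs)), need):
        A = np.vstack([S] + [ineqs[i][0] for i in combo])
        b = np.concatenate([np.zeros(S.shape[0]), [ineqs[i][1] for i in combo]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > 1e-8:
            continue
        if feasible(v):
            vertices.append(v)
    return vertices


def fva_by_enumeration(model, fraction):
    """FVA endpoints for every reaction by exhaustive vertex enumeration."""
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    obj = model.reaction_index(model.objective_id)
    base = enumerate_vertices(S, lb, ub)
    assert base, "oracle: infeasible base polytope"
    z_opt = max(v[obj] for v in base)
    c = np.zeros(n)
    c[obj] = 1.0
    verts = enumerate_vertices(S, lb, ub, floor=(c, fraction * z_opt))
    assert verts, "oracle: infeasible optimality-floor polytope"
    out = {}
    for j, rid in enumerate(model.reaction_ids):
        vals = [v[j] for v in verts]
        out[rid] = (min(vals), max(vals))
    return z_opt, out
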