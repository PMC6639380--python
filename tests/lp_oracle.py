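"""Brute-force LP oracle: enumerate basic feasible solutions of
{S v = 0, lb <= v <= ub} by fixing subsets of variables at their bounds and
solving the remaining square system. Independent of the solver under test;
only usable on tiny models (<= 8 reactions)."""

from __future__ import annotations

import itertools

import numpy as np

TOL = 1e-7


def enumerate_vertices(S, lb, ub, extra_eq=None, extra_rhs=None):
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if extra_eq is not None:
        A = np.vstack([S, np.atleast_2d(extra_eq)])
        b = np.concatenate([np.zeros(S.shape[0]), np.atleast_1d(extra_rhs)])
    else:
        A = S
        b = np.zeros(S.shape[0])
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    n_fixed = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A_free = A[:, free]
        if free and np.linalg.matrix_rank(A_free) < rank:
            continue
        bound_choices = itertools.product(
            *[(lb[j], ub[j]) for j in fixed]
        ) if fixed else [()]
        for choice in bound_choices:
            if any(not np.isfinite(v) for v in choice):
                continue
            rhs = b - (A[:, fixed] @ np.array(choice) if fixed else 0.0)
            if free:
                x_free, residual, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                if np.linalg.norm(A_free @ x_free - rhs) > TOL:
                    continue
            else:
                x_free = np.array([])
                if np.linalg.norm(rhs) > TOL:
                    continue
            x = np.empty(n)
            x[list(fixed)] = choice
            x[free] = x_free
            if np.all(x >= lb - TOL) and np.all(x <= ub + TOL):
                vertices.append(np.clip(x, lb, ub))
    # deduplicate
    unique = []
    for v in vertices:
        if not any(np.allclose(v, u, atol=1e-6) for u in unique):
            unique.append(v)
    return unique


def fba_oracle(model):
    """(optimal objective, list of optimal vertices) by enumeration."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_vector()
    verts = enumerate_vertices(S, lb, ub)
    assert verts, "oracle found no feasible vertex"
    objs = [float(c @ v) for v in verts]
    best = max(objs)
    return best, [v for v, o in zip(verts, objs) if o >= best - TOL]


def pfba_oracle(model):
    """(optimal objective, minimal total |flux| at that objective).

    Valid for irreversible fixtures, where total flux is linear and its
    minimum over the optimal face is attained at an enumerated vertex.
    """
    lb, _ = model.bounds_arrays()
    assert np.all(lb >= 0), "pfba_oracle requires an irreversible fixture"
    best, _ = fba_oracle(model)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_vector()
    verts = enumerate_vertices(S, lb, ub, extra_eq=c, extra_rhs=best)
    assert verts, "oracle found no optimal vertex"
    return best, min(float(np.abs(v).sum()) for v in verts)
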