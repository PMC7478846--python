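"""Brute-force reference for FVA on tiny networks, via vertex enumeration.

A linear program over the bounded polytope {v : S·v = 0, lb <= v <= ub,
v_obj >= floor} attains its optimum at a vertex.  For networks with at most
~8 reactions every vertex can be enumerated exhaustively: a vertex is the
unique solution of the steady-state equalities plus enough active inequality
rows (bounds or the biomass floor) to pin down all degrees of freedom.  This
module enumerates all such candidate active sets, keeps the feasible
solutions, and reads envelope bounds straight off the vertex list — a path
entirely independent of the LP solver used by the engine.

Only meaningful for models whose bounds are all finite (bounded polytope).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .fva import LinearFluxTarget, _lp_arrays
from .model import MetabolicModel

__all__ = ["enumerate_vertices", "fva_by_vertex_enumeration", "fba_optimum_by_vertex_enumeration"]

_TOL = 1e-9


def enumerate_vertices(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    extra_ineq: tuple[np.ndarray, float] | None = None,
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub, a·v >= b (optional)}.

    Returns an array of shape (n_vertices, n).  Requires finite bounds.
    """
    n = S.shape[1]
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration requires finite bounds")
    # inequality rows in the form g·v <= h
    rows: list[tuple[np.ndarray, float]] = []
    eye = np.eye(n)
    for i in range(n):
        rows.append((eye[i], ub[i]))        # v_i <= ub_i
        rows.append((-eye[i], -lb[i]))      # v_i >= lb_i
    if extra_ineq is not None:
        a, b = extra_ineq
        rows.append((-np.asarray(a, float), -float(b)))  # a·v >= b
    G = np.array([g for g, _ in rows])
    h = np.array([c for _, c in rows])

    rank_S = np.linalg.matrix_rank(S, tol=1e-10) if S.size else 0
    k = n - rank_S  # active inequalities needed to pin down a vertex
    verts: list[np.ndarray] = []
    for idx in combinations(range(len(rows)), k):
        M = np.vstack([S, G[list(idx)]]) if S.size else G[list(idx)]
        rhs = np.concatenate([np.zeros(S.shape[0]), h[list(idx)]])
        if np.linalg.matrix_rank(M, tol=1e-10) < n:
            continue
        v, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        if np.max(np.abs(M @ v - rhs)) > 1e-7:
            continue
        if S.size and np.max(np.abs(S @ v)) > 1e-7:
            continue
        if np.any(G @ v - h > 1e-7):
            continue
        verts.append(v)
    if not verts:
        return np.empty((0, n))
    V = np.array(verts)
    # dedupe
    _, keep = np.unique(np.round(V, 6), axis=0, return_index=True)
    return V[np.sort(keep)]


def fba_optimum_by_vertex_enumeration(model: MetabolicModel) -> float:
    """Maximum objective flux, read off the vertex list (nan if infeasible)."""
    S, bounds, rids, ridx = _lp_arrays(model)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    V = enumerate_vertices(S, lb, ub)
    if V.shape[0] == 0:
        return float("nan")
    return float(np.max(V[:, ridx[model.objective_reaction]]))


def fva_by_vertex_enumeration(
    model: MetabolicModel,
    targets: Sequence[LinearFluxTarget | str],
    fraction: float = 0.99,
) -> dict[str, tuple[float, float]]:
    """Reference FVA envelopes {target name: (min, max)} by exhaustion."""
    S, bounds, rids, ridx = _lp_arrays(model)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    opt = fba_optimum_by_vertex_enumeration(model)
    if not np.isfinite(opt):
        raise ValueError("model is infeasible")
    obj_row = np.zeros(len(rids))
    obj_row[ridx[model.objective_reaction]] = 1.0
    V = enumerate_vertices(S, lb, ub, extra_ineq=(obj_row, fraction * opt))
    out: dict[str, tuple[float, float]] = {}
    for tgt in targets:
        if isinstance(tgt, str):
            tgt = LinearFluxTarget.single(tgt)
        w = np.zeros(len(rids))
        for rid, coef in tgt.weights.items():
            w[ridx[rid]] = coef
        vals = V @ w
        out[tgt.name] = (float(np.min(vals)), float(np.max(vals)))
    return out
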