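"""Independent brute-force oracles used to cross-check the LP and statistics
layers.  Everything here is deliberately naive -- exhaustive enumeration and
textbook definitions -- and shares no code with the implementation paths it
checks."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product
from math import comb

import numpy as np


def enumerate_vertices(S, lb, ub, tol=1e-7):
    """All vertices of {v : S v = 0, lb <= v <= ub} by exhaustive basis
    enumeration.  Feasible only for a handful of reactions (the number of
    candidate bases grows combinatorially)."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if m else 0
    k = n - r  # variables pinned at a bound in a basic solution
    vertices = []
    for fixed in combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free] if free else np.zeros((m, 0))
        if free and np.linalg.matrix_rank(A) < len(free):
            continue
        for vals in product(*[(lb[j], ub[j]) for j in fixed]):
            vals = np.array(vals)
            b = -S[:, list(fixed)] @ vals if k else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                if np.linalg.norm(A @ sol - b) > tol:
                    continue
            else:
                sol = np.empty(0)
                if np.linalg.norm(b) > tol:
                    continue
            v = np.empty(n)
            v[list(fixed)] = vals
            v[free] = sol
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(v)
    return np.array(vertices)


def fva_by_vertex_enumeration(S, lb, ub):
    """(min, max) flux per reaction over the enumerated vertex set."""
    verts = enumerate_vertices(S, lb, ub)
    assert len(verts) > 0, "infeasible or degenerate toy network"
    return verts.min(axis=0), verts.max(axis=0)


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher p by full enumeration over fixed margins, in exact
    rational arithmetic: sum of point probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point(x)
        if p <= p_obs:
            total += p
    return total


def ranksum_two_sided_exact(x, y) -> float:
    """Two-sided rank-sum p by enumerating every assignment of pooled ranks
    to the smaller sample (ties not supported)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires no ties"
    ranks = pooled.argsort().argsort() + 1
    rx = ranks[: len(x)].sum()
    n, nx = len(pooled), len(x)
    all_ranks = np.arange(1, n + 1)
    # center: U statistic of x; two-sided p doubles the smaller tail of W
    mean_w = nx * (n + 1) / 2
    stat_obs = abs(rx - mean_w)
    hits = total = 0
    for subset in combinations(all_ranks, nx):
        total += 1
        if abs(sum(subset) - mean_w) >= stat_obs - 1e-12:
            hits += 1
    return hits / total


def bh_adjust_bruteforce(p):
    """Benjamini-Hochberg q-values straight from the step-up definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return np.minimum(q, 1.0)


def model_to_arrays(model):
    """Stoichiometric matrix and bounds of a cobra model, reaction-ordered."""
    rxns = list(model.reactions)
    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(mets), len(rxns)))
    lb = np.array([r.lower_bound for r in rxns])
    ub = np.array([r.upper_bound for r in rxns])
    for j, r in enumerate(rxns):
        for met, coef in r.metabolites.items():
            S[mets[met.id], j] = coef
    return S, lb, ub, [r.id for r in rxns]
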