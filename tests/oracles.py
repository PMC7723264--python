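"""Independent brute-force oracles used only by the tests."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def circumcircle(a, b, c):
    """Center and squared radius of the circle through a, b, c, or None if
    the points are (near-)collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def delaunay_edges_bruteforce(points, max_edge=np.inf) -> set[tuple[int, int]]:
    """O(n^4) empty-circumcircle Delaunay: a triangle belongs to the
    triangulation iff no other point lies strictly inside its circumcircle;
    its edges (no longer than max_edge) form the edge set."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    if n == 2:
        if np.hypot(*(pts[0] - pts[1])) <= max_edge:
            edges.add((0, 1))
        return edges
    for i, j, k in combinations(range(n), 3):
        cc = circumcircle(pts[i], pts[j], pts[k])
        if cc is None:
            continue
        (ux, uy), r2 = cc
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 < r2 - 1e-9:
                empty = False
                break
        if not empty:
            continue
        for a, b in ((i, j), (j, k), (i, k)):
            if np.hypot(*(pts[a] - pts[b])) <= max_edge:
                edges.add((min(a, b), max(a, b)))
    return edges


def optimal_link_pairs(prev, cur, max_disp) -> set[tuple[int, int]]:
    """Minimum-total-distance assignment between two detection sets,
    discarding pairs farther than max_disp (Hungarian algorithm)."""
    from scipy.optimize import linear_sum_assignment

    prev = np.asarray(prev, dtype=float)
    cur = np.asarray(cur, dtype=float)
    cost = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
    big = 1e9
    cost = np.where(cost <= max_disp, cost, big)
    rows, cols = linear_sum_assignment(cost)
    return {(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < big}


def ols_closed_form(x, y):
    """Normal-equation OLS slope/intercept and R²."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return float(beta[1]), float(beta[0]), float(r2)


def branching_cycle_fraction(hazard, n_sg2_steps, n_cells=2000, n_steps=240,
                             burn_in=120, seed=0) -> float:
    """Direct stochastic simulation of the G1/S-G2 division cycle: per step a
    G1 cell switches with probability ``hazard``; an S/G2 cell divides into
    two G1 cells after ``n_sg2_steps`` steps.  Returns the time-averaged
    S/G2 fraction after burn-in (the oracle for the hazard calibration)."""
    rng = np.random.default_rng(seed)
    age = np.full(n_cells, -1, dtype=int)  # -1 = G1, else S/G2 age in steps
    fractions = []
    for step in range(n_steps):
        g1 = age < 0
        switch = g1 & (rng.random(age.size) < hazard)
        age[switch] = 0
        in_s = age >= 0
        age[in_s] += 1
        due = age >= n_sg2_steps
        n_div = int(due.sum())
        if n_div:
            age[due] = -1
            age = np.concatenate([age, np.full(n_div, -1, dtype=int)])
        if step >= burn_in:
            fractions.append((age >= 0).mean())
        if age.size > 200_000:  # keep memory bounded; subsample uniformly
            age = rng.choice(age, size=100_000, replace=False)
    return float(np.mean(fractions))
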