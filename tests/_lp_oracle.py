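"""Brute-force vertex enumeration for small LPs: an independent oracle for
linear programs of the form  min c'x  s.t.  A_eq x = b, lb <= x <= ub.

Every vertex of the polytope is a basic solution: choose m basic columns
(m = number of equality rows), fix each non-basic variable at one of its
bounds, and solve the square system. Exponential, so only for instances with
a handful of variables.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(A_eq, b_eq, lb, ub, tol=1e-9):
    A = np.asarray(A_eq, dtype=float)
    b = np.asarray(b_eq, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = A.shape
    vertices = []
    for basis in itertools.combinations(range(n), m):
        B = A[:, basis]
        if abs(np.linalg.det(B)) < 1e-12:
            continue
        nonbasic = [j for j in range(n) if j not in basis]
        for pattern in itertools.product((0, 1), repeat=len(nonbasic)):
            x = np.empty(n)
            for j, at_ub in zip(nonbasic, pattern):
                x[j] = ub[j] if at_ub else lb[j]
            if not np.all(np.isfinite(x[nonbasic])):
                continue
            rhs = b - A[:, nonbasic] @ x[nonbasic]
            x_b = np.linalg.solve(B, rhs)
            x[list(basis)] = x_b
            if np.all(x >= lb - tol) and np.all(x <= ub + tol):
                vertices.append(x)
    return vertices


def brute_force_optimum(c, A_eq, b_eq, lb, ub, sense="min"):
    verts = enumerate_vertices(A_eq, b_eq, lb, ub)
    if not verts:
        raise ValueError("no feasible vertex found")
    values = [float(np.dot(c, v)) for v in verts]
    return min(values) if sense == "min" else max(values)
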