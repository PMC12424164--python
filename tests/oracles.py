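"""Independent brute-force oracles used by the tests.

The vertex-enumeration oracle solves max c^T v over {S v = 0, lb <= v <= ub}
by enumerating candidate basic solutions: every choice of n - rank(S)
coordinates pinned at a lower or upper bound, with the remaining square
equality system solved directly.  Exponential, therefore only for tiny
networks (<= 8 reactions) with finite bounds — it shares no code with the
LP path it cross-checks.
"""

from itertools import combinations, product

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9):
    """All vertices of the flux polytope (finite bounds required)."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    vertices = []
    for fixed_idx in combinations(range(n), n_fix):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        for choices in product((0, 1), repeat=n_fix):
            v = np.zeros(n)
            for j, side in zip(fixed_idx, choices):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, fixed_idx] @ v[list(fixed_idx)] if n_fix else np.zeros(S.shape[0])
            if free_idx:
                sol, residuals, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
                if np.linalg.norm(A @ sol - rhs) > tol:
                    continue  # inconsistent combination
                v[free_idx] = sol
            elif np.linalg.norm(rhs) > tol:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                if np.abs(S @ v).max() <= tol if S.size else True:
                    vertices.append(v)
    return vertices


def brute_force_fba(S, lb, ub, c, direction="max", tol: float = 1e-9):
    """Optimal objective over the polytope via vertex enumeration; None if
    the polytope is empty."""
    c = np.asarray(c, dtype=float)
    vertices = enumerate_vertices(S, lb, ub, tol=tol)
    if not vertices:
        return None
    values = [float(c @ v) for v in vertices]
    return max(values) if direction == "max" else min(values)
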