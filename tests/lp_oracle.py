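"""Brute-force LP oracle: maximize c·v over {S v = 0, lb <= v <= ub} by
enumerating candidate vertices of the (bounded) feasible polytope.

At a vertex every variable is either pinned to one of its bounds or
determined uniquely by the balance equations; with n <= 6 variables all
3^n pin/free assignments can be enumerated exhaustively.  Independent of
scipy.optimize.linprog, which the implementation under test uses.
"""

from itertools import product

import numpy as np

_TOL = 1e-9


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> list[np.ndarray]:
    n = S.shape[1]
    vertices = []
    for assignment in product((0, 1, 2), repeat=n):  # 0 free, 1 at lb, 2 at ub
        free = [j for j, a in enumerate(assignment) if a == 0]
        fixed_vals = np.where(
            np.array(assignment) == 1, lb, np.where(np.array(assignment) == 2, ub, 0.0)
        )
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A, tol=1e-10) < len(free):
                continue  # free block underdetermined: not a vertex
            rhs = -S @ np.where(np.array(assignment) == 0, 0.0, fixed_vals)
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = fixed_vals.copy()
            v[free] = sol
        else:
            v = fixed_vals
        if np.max(np.abs(S @ v)) > 1e-8:
            continue
        if np.any(v < lb - _TOL) or np.any(v > ub + _TOL):
            continue
        vertices.append(np.clip(v, lb, ub))
    return vertices


def brute_force_max(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray
) -> float | None:
    """Optimal value of max c·v, or None if no vertex is feasible."""
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    return max(float(c @ v) for v in vertices)
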