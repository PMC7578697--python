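"""Independent brute-force solver for tiny soft-margin SVM instances.

Enumerates every KKT active-set assignment (each training point's dual
variable at 0, at C, or free), solves the resulting linear system, and
returns the smallest primal objective over all box-feasible candidates.
Exponential in n, usable up to ~10 points; shares no code with the
package's SMO solver.
"""

from __future__ import annotations

import itertools

import numpy as np


def primal_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
                     C: float) -> float:
    margins = 1.0 - y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.clip(margins, 0.0, None).sum())


def _best_bias(w: np.ndarray, X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Exact minimizer over b of the piecewise-linear hinge sum."""
    kinks = y - X @ w  # b values where some margin is exactly 1
    cands = np.concatenate([kinks, [0.0]])
    objs = [primal_objective(w, b, X, y, C) for b in cands]
    return float(cands[int(np.argmin(objs))])


def brute_force_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float, float]:
    """(w, b, objective) of the exact soft-margin optimum, by enumeration."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = X @ X.T
    best = (None, None, np.inf)
    for assign in itertools.product((0, 1, 2), repeat=n):  # 0, C, free
        free = [i for i, a in enumerate(assign) if a == 2]
        alpha = np.array([C if a == 1 else 0.0 for a in assign])
        if free:
            # margins of free SVs are exactly 1, plus the equality constraint
            m = len(free)
            A = np.zeros((m + 1, m + 1))
            rhs = np.zeros(m + 1)
            for r, i in enumerate(free):
                for c, j in enumerate(free):
                    A[r, c] = y[i] * y[j] * K[i, j]
                A[r, m] = y[i]
                rhs[r] = 1.0 - y[i] * sum(
                    alpha[j] * y[j] * K[i, j] for j in range(n) if assign[j] == 1
                )
            A[m, :m] = [y[i] for i in free]
            rhs[m] = -sum(alpha[j] * y[j] for j in range(n) if assign[j] == 1)
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            af, b = sol[:m], float(sol[m])
            if np.any(af < -1e-9) or np.any(af > C + 1e-9):
                continue
            alpha[free] = np.clip(af, 0.0, C)
            w = X.T @ (alpha * y)
        else:
            if abs(alpha @ y) > 1e-9:
                continue
            w = X.T @ (alpha * y)
            b = _best_bias(w, X, y, C)
        obj = primal_objective(w, b, X, y, C)
        if obj < best[2]:
            best = (w, b, obj)
    return best
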