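"""Thin wrappers around scipy's HiGHS linear and mixed-integer solvers."""

from __future__ import annotations

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    pass


def solve_lp(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None):
    """Minimize ``c @ x``; returns ``(status, x, objective)``.

    ``bounds`` is a sequence of (lo, hi) pairs.  Statuses other than
    optimal/infeasible/unbounded raise :class:`SolverError`.
    """
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 0:
        return OPTIMAL, res.x, res.fun
    if res.status == 2:
        return INFEASIBLE, None, None
    if res.status == 3:
        return UNBOUNDED, None, None
    raise SolverError(f"LP solver failure: {res.message}")


def solve_milp(c, integrality, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
               bounds=None):
    """Minimize ``c @ x`` with per-variable integrality flags (0/1 arrays)."""
    constraints = []
    if A_eq is not None and len(A_eq):
        constraints.append(LinearConstraint(np.asarray(A_eq), b_eq, b_eq))
    if A_ub is not None and len(A_ub):
        constraints.append(
            LinearConstraint(np.asarray(A_ub), -np.inf, b_ub))
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    res = milp(np.asarray(c, dtype=float), constraints=constraints,
               integrality=np.asarray(integrality),
               bounds=Bounds(lo, hi))
    if res.status == 0:
        return OPTIMAL, res.x, res.fun
    if res.status == 2:
        return INFEASIBLE, None, None
    if res.status == 3:
        return UNBOUNDED, None, None
    raise SolverError(f"MILP solver failure: {res.message}")
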