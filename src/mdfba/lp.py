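"""Solver-agnostic linear/mixed-integer program contract.

Problems are built symbolically (named variables, dict-of-coefficients
constraints) and solved through HiGHS via :func:`scipy.optimize.milp`, which
handles both pure LPs and MILPs.  Only status and primal values are reported;
no duals are needed anywhere in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as _scipy_milp

INF = float("inf")

#: status vocabulary shared by every solve in the package
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
ERROR = "error"

_STATUS_MAP = {0: OPTIMAL, 1: ERROR, 2: INFEASIBLE, 3: UNBOUNDED, 4: ERROR}


@dataclass
class Variable:
    name: str
    lower: float = -INF
    upper: float = INF
    integer: bool = False


@dataclass
class Constraint:
    coefficients: Dict[str, float]
    relation: str  # "<=", "=", ">="
    constant: float
    name: str = ""


@dataclass
class LinearProgram:
    variables: List[Variable] = field(default_factory=list)
    constraints: List[Constraint] = field(default_factory=list)
    objective: Dict[str, float] = field(default_factory=dict)
    sense: str = "max"

    def add_variable(
        self,
        name: str,
        lower: float = -INF,
        upper: float = INF,
        integer: bool = False,
    ) -> Variable:
        var = Variable(name, lower, upper, integer)
        self.variables.append(var)
        return var

    def add_constraint(
        self,
        coefficients: Dict[str, float],
        relation: str,
        constant: float,
        name: str = "",
    ) -> None:
        if relation not in ("<=", "=", ">="):
            raise ValueError(f"bad relation {relation!r}")
        self.constraints.append(Constraint(dict(coefficients), relation, constant, name))


@dataclass
class LPSolution:
    status: str
    objective_value: Optional[float]
    values: Dict[str, float]
    gap: Optional[float] = None
    message: str = ""


def solve_linear_program(
    problem: LinearProgram,
    mip_gap: Optional[float] = None,
    time_limit: Optional[float] = None,
) -> LPSolution:
    """Solve with HiGHS; maximization handled by objective negation."""
    names = [v.name for v in problem.variables]
    index = {n: i for i, n in enumerate(names)}
    if len(index) != len(names):
        raise ValueError("duplicate variable names")
    n = len(names)
    c = np.zeros(n)
    for name, coeff in problem.objective.items():
        c[index[name]] = coeff
    sign = -1.0 if problem.sense == "max" else 1.0
    integrality = np.array([1 if v.integer else 0 for v in problem.variables])
    bounds = Bounds(
        np.array([v.lower for v in problem.variables]),
        np.array([v.upper for v in problem.variables]),
    )
    constraints = []
    if problem.constraints:
        data, ii, jj, lo, hi = [], [], [], [], []
        for i, con in enumerate(problem.constraints):
            for name, coeff in con.coefficients.items():
                ii.append(i)
                jj.append(index[name])
                data.append(coeff)
            if con.relation == "<=":
                lo.append(-INF)
                hi.append(con.constant)
            elif con.relation == ">=":
                lo.append(con.constant)
                hi.append(INF)
            else:
                lo.append(con.constant)
                hi.append(con.constant)
        A = sparse.csr_matrix(
            (data, (ii, jj)), shape=(len(problem.constraints), n)
        )
        constraints = [LinearConstraint(A, np.array(lo), np.array(hi))]
    options: Dict[str, object] = {
        "disp": False,
        "output_flag": False,
        # big-M rows amplify solver slack by the bound magnitude (~1e3), so
        # keep feasibility/integrality tolerances well below default
        "primal_feasibility_tolerance": 1e-9,
        "dual_feasibility_tolerance": 1e-9,
    }
    if integrality.any():
        options["mip_feasibility_tolerance"] = 1e-9
        if mip_gap is not None:
            options["mip_rel_gap"] = mip_gap
    if time_limit is not None:
        options["time_limit"] = time_limit
    with warnings.catch_warnings():
        # scipy warns that non-core options are passed to HiGHS verbatim
        warnings.filterwarnings("ignore", message="Unrecognized options")
        res = _scipy_milp(
            sign * c,
            constraints=constraints,
            integrality=integrality,
            bounds=bounds,
            options=options,
        )
    status = _STATUS_MAP.get(res.status, ERROR)
    if status == OPTIMAL and res.x is None:  # defensive: HiGHS edge case
        status = ERROR
    if status != OPTIMAL:
        return LPSolution(status, None, {}, message=str(res.message))
    values = {name: float(res.x[i]) for name, i in index.items()}
    gap = float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else None
    return LPSolution(status, float(sign * res.fun), values, gap=gap,
                      message=str(res.message))
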