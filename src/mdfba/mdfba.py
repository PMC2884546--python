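"""Metabolite-dilution flux balance analysis (MD-FBA).

MD-FBA replaces FBA's strict steady state with a mass balance that drains
every *active* internal metabolite at a growth-proportional dilution rate.
For each internal metabolite j the MILP carries a dilution variable
``d_j >= 0`` and a binary activity indicator ``y_j``:

  balance      sum_i S_ji v_i - d_j = 0
  indicator    v_i <= eps + (ub_i - eps) y_j     for producers (S_ji > 0)
               -v_i <= eps + (-lb_i - eps) y_j   for reversible consumers
                                                  (S_ji < 0, lb_i < 0)
  dilution     d_j >= eps * mu - M (1 - y_j)     (mu-coupled; M = eps * mu_cap)
               d_j >= eps * y_j                  (simplified unit-mu variant)

with the biomass flux mu maximized.  A metabolite produced by any reaction at
a rate above the activity threshold eps is thereby forced to carry a dilution
flux of at least eps*mu, which in turn forces net synthesis of the metabolite
— the mechanism that activates co-factor biosynthesis pathways FBA leaves
silent, and that starves futile cycles with no production route down to
fluxes of at most eps.

The big-M linearization cannot encode strict inequalities: fluxes up to eps
never trip an indicator, so an "inactive" network can still leak a growth
rate of up to eps.  All zero-growth statements hold at that resolution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from . import lp
from .lp import INF, LinearProgram, solve_linear_program
from .network import MetabolicNetwork, compute_scope, medium_seeds

MU_COUPLED = "mu_coupled"
UNIT_MU = "unit_mu"

#: brute-force enumeration cap (2^m LPs)
BRUTE_FORCE_MAX_METABOLITES = 14


@dataclass
class MDFBAConfig:
    """Tunables of the MD-FBA MILP.

    epsilon
        Activity threshold and dilution coefficient (flux units per unit
        growth).  1e-4 corresponds to a typical intermediate-metabolite
        concentration of 1e-4 umol/mg.  Zero is allowed as a degenerate
        setting in which every dilution demand vanishes and MD-FBA relaxes
        to FBA.
    coupling_mode
        ``mu_coupled`` (dilution floor eps*mu) or ``unit_mu`` (simplified
        constant floor eps, i.e. growth fixed at 1 in the dilution term).
    mu_upper
        Cap on the growth rate; sets the dilution big-M (eps * mu_upper).
    indicator_slack
        Tolerance used when *checking* indicator semantics: a producing flux
        above eps + slack must have tripped its indicator.
    use_scope_reduction
        Fix y_j = 0 (no binary) for metabolites outside the medium's
        producibility scope — they can never satisfy a dilution demand.
    milp_gap
        Relative MILP optimality gap requested from the solver.
    """

    epsilon: float = 1e-4
    coupling_mode: str = MU_COUPLED
    mu_upper: float = 1000.0
    indicator_slack: float = 1e-9
    use_scope_reduction: bool = False
    milp_gap: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.coupling_mode not in (MU_COUPLED, UNIT_MU):
            raise ValueError(f"unknown coupling mode {self.coupling_mode!r}")
        if self.epsilon * self.mu_upper >= 1.0:
            warnings.warn(
                "epsilon * mu_upper >= 1: outside the eps*mu < 1 regime the "
                "linearization assumes",
                stacklevel=2,
            )


@dataclass
class MDFBASolution:
    """MD-FBA optimum: fluxes v, dilutions d, activity indicators y, growth mu."""

    fluxes: Dict[str, float] = field(default_factory=dict)
    dilution: Dict[str, float] = field(default_factory=dict)
    activity: Dict[str, int] = field(default_factory=dict)
    mu: Optional[float] = None
    status: str = lp.ERROR
    gap: Optional[float] = None

    @property
    def growth(self) -> float:
        """mu as a plain number, zero when the problem was not solved."""
        return self.mu if (self.mu is not None and self.status == lp.OPTIMAL) else 0.0


def _dilution_metabolites(network: MetabolicNetwork) -> List[str]:
    """Internal metabolites that get a balance row (participate somewhere)."""
    used: Set[str] = set()
    for r in network.reactions:
        used |= set(r.stoichiometry)
    return [m.id for m in network.internal_metabolites if m.id in used]


def _mu_cap(network: MetabolicNetwork, config: MDFBAConfig) -> float:
    ub = network.biomass_reaction.upper_bound
    return min(config.mu_upper, ub) if np.isfinite(ub) else config.mu_upper


def build_mdfba_problem(
    network: MetabolicNetwork,
    config: Optional[MDFBAConfig] = None,
    scope: Optional[Set[str]] = None,
) -> LinearProgram:
    """Assemble the MD-FBA MILP for a (condition-applied) network.

    ``scope`` restricts binaries when ``config.use_scope_reduction`` is set;
    if not given it is computed from the open exchanges.  Metabolites outside
    the scope get their indicator fixed to zero (producing fluxes capped at
    eps) and no binary variable.
    """
    config = config or MDFBAConfig()
    eps = config.epsilon
    for r in network.reactions:
        if not np.isfinite(r.lower_bound) or not np.isfinite(r.upper_bound):
            raise ValueError(f"reaction {r.id}: non-finite bounds")
    mets = _dilution_metabolites(network)
    if config.use_scope_reduction and scope is None:
        scope = compute_scope(network, medium_seeds(network))

    problem = LinearProgram(sense="max")
    biomass = network.biomass_reaction_id
    mu_cap = _mu_cap(network, config)
    for r in network.reactions:
        ub = min(r.upper_bound, mu_cap) if r.id == biomass else r.upper_bound
        problem.add_variable(r.id, r.lower_bound, ub)

    in_scope = {m: (scope is None or m in scope) for m in mets}
    for met in mets:
        problem.add_variable(f"d[{met}]", 0.0, INF)
        if in_scope[met]:
            problem.add_variable(f"y[{met}]", 0.0, 1.0, integer=True)

    for met in mets:
        coeffs = {r.id: r.stoichiometry[met] for r in network.reactions_of(met)}
        coeffs[f"d[{met}]"] = -1.0
        problem.add_constraint(coeffs, "=", 0.0, name=f"balance[{met}]")

        y = f"y[{met}]" if in_scope[met] else None
        for r in network.reactions_of(met):
            coeff = r.stoichiometry[met]
            if coeff > 0 and r.upper_bound > 0:
                if r.upper_bound <= eps:
                    warnings.warn(
                        f"reaction {r.id}: upper bound <= epsilon, activity "
                        f"indicator for {met} is vacuous",
                        stacklevel=2,
                    )
                if y is None:
                    problem.add_constraint({r.id: 1.0}, "<=", eps)
                else:
                    problem.add_constraint(
                        {r.id: 1.0, y: -(r.upper_bound - eps)}, "<=", eps,
                        name=f"ind+[{met},{r.id}]",
                    )
            if coeff < 0 and r.lower_bound < 0:
                if y is None:
                    problem.add_constraint({r.id: -1.0}, "<=", eps)
                else:
                    problem.add_constraint(
                        {r.id: -1.0, y: -(-r.lower_bound - eps)}, "<=", eps,
                        name=f"ind-[{met},{r.id}]",
                    )

        if y is not None and eps > 0:
            # Rows are stated in units of growth rate (divided through by
            # eps) so the floor is O(mu), not O(eps*mu) — otherwise a tiny
            # optimum slips under the solver's feasibility tolerance.
            if config.coupling_mode == MU_COUPLED:
                # d/eps >= mu - mu_cap * (1 - y)
                problem.add_constraint(
                    {f"d[{met}]": 1.0 / eps, biomass: -1.0, y: -mu_cap},
                    ">=",
                    -mu_cap,
                    name=f"dilution[{met}]",
                )
            else:
                # d/eps >= y
                problem.add_constraint(
                    {f"d[{met}]": 1.0 / eps, y: -1.0}, ">=", 0.0,
                    name=f"dilution[{met}]",
                )

    problem.objective = {biomass: 1.0}
    return problem


def solve_mdfba(
    network: MetabolicNetwork,
    config: Optional[MDFBAConfig] = None,
    parsimonious: bool = True,
) -> MDFBASolution:
    """Solve the MD-FBA MILP; returns fluxes, dilutions, activities and mu.

    By default the flux vector is canonicalized among alternate optima: with
    the activity assignment and the optimal growth rate held fixed, total
    absolute flux is minimized.  Dilution is a free overflow sink, so without
    this step the solver may report gratuitous uptake routed straight into
    dilution; parsimony also makes the reported fluxes deterministic.
    ``parsimonious=False`` returns the raw MILP vertex.
    """
    config = config or MDFBAConfig()
    problem = build_mdfba_problem(network, config)
    sol = solve_linear_program(problem, mip_gap=config.milp_gap)
    if sol.status != lp.OPTIMAL:
        return MDFBASolution(status=sol.status, gap=sol.gap)
    mets = _dilution_metabolites(network)
    fluxes = {r.id: sol.values[r.id] for r in network.reactions}
    dilution = {m: sol.values[f"d[{m}]"] for m in mets}
    activity = {
        m: int(round(sol.values.get(f"y[{m}]", 0.0))) for m in mets
    }
    mu = sol.objective_value
    if parsimonious:
        canon = _parsimonious_fluxes(network, config, activity, mu)
        if canon is not None:
            fluxes, dilution = canon
            mu = fluxes[network.biomass_reaction_id]
    return MDFBASolution(
        fluxes=fluxes,
        dilution=dilution,
        activity=activity,
        mu=mu,
        status=sol.status,
        gap=sol.gap,
    )


def _parsimonious_fluxes(
    network: MetabolicNetwork,
    config: MDFBAConfig,
    activity: Dict[str, int],
    mu_star: float,
) -> Optional[Tuple[Dict[str, float], Dict[str, float]]]:
    """Minimize total |v| over the LP induced by a fixed activity assignment,
    holding biomass at the MILP optimum (tiny relative slack for solver
    tolerance).  Returns None if that LP unexpectedly fails."""
    eps = config.epsilon
    mets = _dilution_metabolites(network)
    biomass = network.biomass_reaction_id
    mu_cap = _mu_cap(network, config)
    problem = LinearProgram(sense="min")
    objective: Dict[str, float] = {}
    for r in network.reactions:
        ub = min(r.upper_bound, mu_cap) if r.id == biomass else r.upper_bound
        lb = r.lower_bound
        for met, coeff in r.stoichiometry.items():
            if met in activity and activity[met] == 0:
                if coeff > 0:
                    ub = min(ub, eps)
                if coeff < 0 and r.lower_bound < 0:
                    lb = max(lb, -eps)
        if lb > ub:
            return None
        problem.add_variable(r.id, lb, ub)
        t = f"abs[{r.id}]"
        problem.add_variable(t, 0.0, INF)
        problem.add_constraint({t: 1.0, r.id: -1.0}, ">=", 0.0)
        problem.add_constraint({t: 1.0, r.id: 1.0}, ">=", 0.0)
        objective[t] = 1.0
    for met in mets:
        problem.add_variable(f"d[{met}]", 0.0, INF)
        coeffs = {r.id: r.stoichiometry[met] for r in network.reactions_of(met)}
        coeffs[f"d[{met}]"] = -1.0
        problem.add_constraint(coeffs, "=", 0.0)
        if activity.get(met) == 1 and eps > 0:
            if config.coupling_mode == MU_COUPLED:
                problem.add_constraint(
                    {f"d[{met}]": 1.0 / eps, biomass: -1.0}, ">=", 0.0
                )
            else:
                problem.variables[-1].lower = eps
    problem.add_constraint(
        {biomass: 1.0}, ">=", mu_star - 1e-9 * max(1.0, abs(mu_star))
    )
    problem.objective = objective
    sol = solve_linear_program(problem)
    if sol.status != lp.OPTIMAL:
        return None
    fluxes = {r.id: sol.values[r.id] for r in network.reactions}
    dilution = {m: sol.values[f"d[{m}]"] for m in mets}
    return fluxes, dilution


# ---------------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------------

def brute_force_mdfba(
    network: MetabolicNetwork, config: Optional[MDFBAConfig] = None
) -> MDFBASolution:
    """Exhaustive MD-FBA: enumerate every activity assignment, solve the LP
    each induces, return the best feasible optimum.

    With the indicators fixed, the big-M constraints collapse to plain bound
    tightenings (y_j = 0 caps every producing flux at eps) and, for active
    metabolites, the linear floor ``d_j >= eps * mu`` (or ``eps`` in unit-mu
    mode).  Intended as an independent verification oracle; refuses networks
    with more than 14 internal metabolites.
    """
    config = config or MDFBAConfig()
    eps = config.epsilon
    mets = _dilution_metabolites(network)
    m = len(mets)
    if m > BRUTE_FORCE_MAX_METABOLITES:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_MAX_METABOLITES} internal "
            f"metabolites, got {m}"
        )
    rxns = network.reactions
    n = len(rxns)
    rid = {r.id: j for j, r in enumerate(rxns)}
    bio = rid[network.biomass_reaction_id]
    mu_cap = _mu_cap(network, config)

    base_lb = np.array([r.lower_bound for r in rxns] + [0.0] * m)
    base_ub = np.array(
        [min(r.upper_bound, mu_cap) if j == bio else r.upper_bound
         for j, r in enumerate(rxns)]
        + [INF] * m
    )
    # equality rows: S v - d = 0
    data, ii, jj = [], [], []
    for i, met in enumerate(mets):
        for r in network.reactions_of(met):
            ii.append(i)
            jj.append(rid[r.id])
            data.append(r.stoichiometry[met])
        ii.append(i)
        jj.append(n + i)
        data.append(-1.0)
    A_eq = sparse.csr_matrix((data, (ii, jj)), shape=(m, n + m))
    b_eq = np.zeros(m)
    c = np.zeros(n + m)
    c[bio] = -1.0  # linprog minimizes

    producers: List[List[int]] = []
    rev_consumers: List[List[int]] = []
    for met in mets:
        pro, rev = [], []
        for r in network.reactions_of(met):
            coeff = r.stoichiometry[met]
            if coeff > 0 and r.upper_bound > 0:
                pro.append(rid[r.id])
            if coeff < 0 and r.lower_bound < 0:
                rev.append(rid[r.id])
        producers.append(pro)
        rev_consumers.append(rev)

    best: Optional[Tuple[float, np.ndarray, Tuple[int, ...]]] = None
    for assignment in itertools.product((0, 1), repeat=m):
        lb = base_lb.copy()
        ub = base_ub.copy()
        rows_i, rows_j, rows_v = [], [], []
        row = 0
        for i, y in enumerate(assignment):
            if y == 0:
                for j in producers[i]:
                    ub[j] = min(ub[j], eps)
                for j in rev_consumers[i]:
                    lb[j] = max(lb[j], -eps)
            elif eps > 0:
                if config.coupling_mode == MU_COUPLED:
                    # mu - d_i/eps <= 0 (same eps-scaling as the MILP rows)
                    rows_i += [row, row]
                    rows_j += [bio, n + i]
                    rows_v += [1.0, -1.0 / eps]
                    row += 1
                else:
                    lb[n + i] = max(lb[n + i], eps)
        if np.any(lb > ub):
            continue
        A_ub = (
            sparse.csr_matrix((rows_v, (rows_i, rows_j)), shape=(row, n + m))
            if row
            else None
        )
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=np.zeros(row) if row else None,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 0:
            mu = -res.fun
            if best is None or mu > best[0] + 1e-12:
                best = (mu, res.x, assignment)
    if best is None:
        return MDFBASolution(status=lp.INFEASIBLE)
    mu, x, assignment = best
    return MDFBASolution(
        fluxes={r.id: float(x[rid[r.id]]) for r in rxns},
        dilution={met: float(x[n + i]) for i, met in enumerate(mets)},
        activity={met: int(assignment[i]) for i, met in enumerate(mets)},
        mu=float(mu),
        status=lp.OPTIMAL,
        gap=0.0,
    )


# ---------------------------------------------------------------------------------
# Solution inspection
# ---------------------------------------------------------------------------------

def activity_pattern(solution, flux_tol: float = 1e-6) -> Set[str]:
    """Reaction ids carrying flux above ``flux_tol`` in magnitude.

    Accepts any solution object with a ``fluxes`` mapping (FBA or MD-FBA).
    """
    return {rid for rid, v in solution.fluxes.items() if abs(v) > flux_tol}


def check_solution(
    network: MetabolicNetwork,
    solution: MDFBASolution,
    config: Optional[MDFBAConfig] = None,
    tol_scale: float = 1e-6,
) -> List[str]:
    """Contract checks on an optimal MD-FBA solution; returns violations.

    Verifies the dilution balance (net production of every internal
    metabolite equals d_j), indicator soundness (production above
    eps + slack implies y = 1) and the dilution floor for active metabolites.
    """
    config = config or MDFBAConfig()
    eps = config.epsilon
    problems: List[str] = []
    if solution.status != lp.OPTIMAL:
        return [f"status is {solution.status}"]
    scale = max(1.0, max((abs(v) for v in solution.fluxes.values()), default=1.0))
    tol = tol_scale * scale
    for met, d in solution.dilution.items():
        if d < -tol:
            problems.append(f"{met}: negative dilution {d}")
        net = sum(
            r.stoichiometry[met] * solution.fluxes[r.id]
            for r in network.reactions_of(met)
        )
        if abs(net - d) > tol:
            problems.append(f"{met}: balance residual {net - d:.3g}")
        y = solution.activity.get(met, 0)
        produced = max(
            [
                r.stoichiometry[met] * solution.fluxes[r.id]
                for r in network.reactions_of(met)
                if r.stoichiometry[met] * solution.fluxes[r.id] > 0
            ],
            default=0.0,
        )
        if produced > eps + config.indicator_slack + tol and y != 1:
            problems.append(f"{met}: produced at {produced:.3g} but inactive")
        if y == 1 and config.coupling_mode == MU_COUPLED:
            floor = eps * (solution.mu or 0.0)
            if d < floor - tol:
                problems.append(f"{met}: dilution {d:.3g} below floor {floor:.3g}")
    return problems
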