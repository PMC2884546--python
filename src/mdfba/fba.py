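"""Classic flux balance analysis.

FBA maximizes the biomass flux mu subject to steady-state mass balance
``S v = 0`` over internal metabolites and per-reaction bounds.  A secondary
parsimony objective (:func:`minimize_total_flux`) canonicalizes the activity
pattern among alternate optima by minimizing total absolute flux at a fixed
growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from . import lp
from .lp import INF, LinearProgram, solve_linear_program
from .network import MetabolicNetwork


@dataclass
class FluxDistribution:
    """An FBA solution: flux per reaction, objective mu, solver status."""

    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: Optional[float] = None
    status: str = lp.ERROR

    @property
    def mu(self) -> Optional[float]:
        return self.objective_value


def build_fba_problem(network: MetabolicNetwork) -> LinearProgram:
    """The FBA LP: flux variables with reaction bounds, one balance row per
    internal metabolite, biomass maximization."""
    problem = LinearProgram(sense="max")
    for r in network.reactions:
        problem.add_variable(r.id, r.lower_bound, r.upper_bound)
    for met in network.internal_metabolites:
        coeffs = {
            r.id: r.stoichiometry[met.id] for r in network.reactions_of(met.id)
        }
        if coeffs:
            problem.add_constraint(coeffs, "=", 0.0, name=f"balance[{met.id}]")
    problem.objective = {network.biomass_reaction_id: 1.0}
    return problem


def solve_fba(network: MetabolicNetwork) -> FluxDistribution:
    """Maximize biomass flux under steady-state mass balance."""
    sol = solve_linear_program(build_fba_problem(network))
    if sol.status != lp.OPTIMAL:
        return FluxDistribution(status=sol.status)
    return FluxDistribution(
        fluxes=sol.values, objective_value=sol.objective_value, status=sol.status
    )


def minimize_total_flux(
    network: MetabolicNetwork, fixed_mu: float
) -> FluxDistribution:
    """Among flux vectors with biomass >= ``fixed_mu``, minimize total |v|.

    Absolute values are linearized with auxiliary variables ``t_i >= |v_i|``;
    reversible fluxes therefore need no explicit splitting.
    """
    problem = build_fba_problem(network)
    problem.sense = "min"
    objective: Dict[str, float] = {}
    for r in network.reactions:
        t = f"abs[{r.id}]"
        problem.add_variable(t, 0.0, INF)
        problem.add_constraint({t: 1.0, r.id: -1.0}, ">=", 0.0)
        problem.add_constraint({t: 1.0, r.id: 1.0}, ">=", 0.0)
        objective[t] = 1.0
    problem.add_constraint({network.biomass_reaction_id: 1.0}, ">=", fixed_mu)
    problem.objective = objective
    sol = solve_linear_program(problem)
    if sol.status != lp.OPTIMAL:
        return FluxDistribution(status=sol.status)
    fluxes = {r.id: sol.values[r.id] for r in network.reactions}
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=fluxes[network.biomass_reaction_id],
        status=sol.status,
    )
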