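"""Biomass co-factor reduction.

Co-factors fixed in a model's biomass reaction impose their synthesis in
every condition, even where the pathway that needs them is silent — which
turns into false lethality calls when the co-factor is unproducible on a
medium.  MD-FBA predicts the growth-associated demand for a co-factor
dynamically (through its dilution variable), so a co-factor whose dilution is
predicted in at least one tested condition can be dropped from the biomass
and its demand left to the dilution machinery.

Each candidate is tested one at a time against the original biomass (its own
coefficient zeroed, everything else untouched); candidates with a positive
dilution flag in any condition are then removed jointly.  Decisions are
therefore independent of candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import lp
from .mdfba import MDFBAConfig, solve_mdfba
from .network import Condition, MetabolicNetwork, apply_condition

DILUTION_TOL = 1e-8


@dataclass
class ReductionReport:
    """Per-co-factor dilution flags and the resulting biomass change."""

    flags: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    removed: Dict[str, bool] = field(default_factory=dict)
    reduced_biomass: Dict[str, float] = field(default_factory=dict)


def _without_cofactor(
    network: MetabolicNetwork, cofactor_id: str
) -> MetabolicNetwork:
    out = network.copy()
    biomass = out.biomass_reaction
    if cofactor_id not in biomass.stoichiometry:
        raise ValueError(
            f"co-factor {cofactor_id!r} is not in the biomass reaction"
        )
    del biomass.stoichiometry[cofactor_id]
    return out


def test_cofactor_dilution(
    network: MetabolicNetwork,
    cofactor_id: str,
    conditions: Sequence[Condition],
    config: Optional[MDFBAConfig] = None,
    dilution_tol: float = DILUTION_TOL,
) -> Dict[str, bool]:
    """Does MD-FBA predict dilution of a co-factor once it leaves the biomass?

    The co-factor's biomass coefficient is zeroed on a copy and MD-FBA is
    solved per condition; the flag is whether the co-factor's dilution flux
    exceeds ``dilution_tol`` at the optimum (False when infeasible).
    """
    reduced = _without_cofactor(network, cofactor_id)
    flags: Dict[str, bool] = {}
    for i, cond in enumerate(conditions):
        label = cond.label or f"condition_{i}"
        sol = solve_mdfba(apply_condition(reduced, cond), config)
        flags[label] = (
            sol.status == lp.OPTIMAL
            and sol.dilution.get(cofactor_id, 0.0) > dilution_tol
        )
    return flags


def reduce_biomass(
    network: MetabolicNetwork,
    cofactor_ids: Iterable[str],
    conditions: Sequence[Condition],
    config: Optional[MDFBAConfig] = None,
    dilution_tol: float = DILUTION_TOL,
    min_positive: int = 1,
) -> Tuple[MetabolicNetwork, ReductionReport]:
    """Drop from the biomass every candidate whose dilution is predicted in at
    least ``min_positive`` tested conditions.

    Candidates are each tested against the *original* biomass, then removed
    simultaneously; an empty candidate list is the identity transform.
    """
    report = ReductionReport()
    to_remove: List[str] = []
    for cofactor in cofactor_ids:
        flags = test_cofactor_dilution(
            network, cofactor, conditions, config, dilution_tol
        )
        report.flags[cofactor] = flags
        removed = sum(flags.values()) >= min_positive
        report.removed[cofactor] = removed
        if removed:
            to_remove.append(cofactor)
    out = network.copy()
    biomass = out.biomass_reaction
    for cofactor in to_remove:
        del biomass.stoichiometry[cofactor]
    report.reduced_biomass = dict(biomass.stoichiometry)
    return out, report
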