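"""Programmatic test networks and synthetic phenotype tables.

Everything a test needs is generated in memory: the eight-reaction worked
example with a recycled co-factor pair, a pure futile-cycle variant of it,
seeded random networks with planted co-factor cycles, and noisy measured
growth proxies for exercising the evaluation statistics.  Same seed, same
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import lp
from .mdfba import MDFBAConfig, solve_mdfba
from .fba import solve_fba
from .network import (
    Condition,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    apply_condition,
)
from .gpr import parse_gpr


@dataclass
class FixtureSpec:
    """Knobs of the random-network generator."""

    seed: int = 0
    n_internal_metabolites: int = 8
    n_reactions: int = 10
    n_cofactor_cycles: int = 1
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_reactions < self.n_internal_metabolites:
            raise ValueError("need n_reactions >= n_internal_metabolites")
        if self.n_internal_metabolites < 2 + 2 * self.n_cofactor_cycles:
            raise ValueError("too many co-factor cycles for the metabolite count")


def figure1_network(c_in_biomass: bool = False) -> MetabolicNetwork:
    """The eight-reaction worked example with a recycled co-factor.

    Internal metabolites A, B, C, Cstar, D, X; uptakes v1 (A) and v6 (X);
    an efficient route v4: A + C -> B + Cstar that consumes the co-factor C
    (recycled by v8: Cstar -> C, synthesized de novo via v6/v7) and an
    inefficient route v2: 2 A -> D, v3: D -> B.  Biomass is v5: B ->, so the
    v5 flux is the growth rate.  One gene per reaction (g1..g8); v6-v8 are
    labeled subsystem "cofactor", everything else "core".

    ``c_in_biomass=True`` adds one C per B to the biomass — the variant in
    which fixing the co-factor in the biomass causes false lethality when its
    precursor X is unavailable.
    """
    mets = [
        Metabolite("ext_A", is_boundary=True),
        Metabolite("ext_X", is_boundary=True),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("C", is_cofactor=True),
        Metabolite("Cstar", is_cofactor=True),
        Metabolite("D"),
        Metabolite("X"),
    ]
    biomass_stoich: Dict[str, float] = {"B": -1.0}
    if c_in_biomass:
        biomass_stoich["C"] = -1.0
    rxns = [
        Reaction("v1", {"ext_A": -1.0, "A": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g1"), subsystem="core", is_exchange=True),
        Reaction("v2", {"A": -2.0, "D": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g2"), subsystem="core"),
        Reaction("v3", {"D": -1.0, "B": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g3"), subsystem="core"),
        Reaction("v4", {"A": -1.0, "C": -1.0, "B": 1.0, "Cstar": 1.0}, 0.0,
                 1000.0, gpr=parse_gpr("g4"), subsystem="core"),
        Reaction("v5", biomass_stoich, 0.0, 1000.0,
                 gpr=parse_gpr("g5"), subsystem="core"),
        Reaction("v6", {"ext_X": -1.0, "X": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g6"), subsystem="cofactor", is_exchange=True),
        Reaction("v7", {"X": -1.0, "C": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g7"), subsystem="cofactor"),
        Reaction("v8", {"Cstar": -1.0, "C": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g8"), subsystem="cofactor"),
    ]
    return MetabolicNetwork(mets, rxns, "v5")


def futile_cycle_network() -> MetabolicNetwork:
    """The worked example stripped to its futile cycle.

    Only the uptake of A, the co-factor-dependent route v4, the recycling
    reaction v8 and the biomass remain: C has no synthesis route, so FBA can
    still grow by spinning the v4/v8 cycle while MD-FBA cannot satisfy the
    co-factor's dilution demand.
    """
    mets = [
        Metabolite("ext_A", is_boundary=True),
        Metabolite("A"),
        Metabolite("B"),
        Metabolite("C", is_cofactor=True),
        Metabolite("Cstar", is_cofactor=True),
    ]
    rxns = [
        Reaction("v1", {"ext_A": -1.0, "A": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g1"), subsystem="core", is_exchange=True),
        Reaction("v4", {"A": -1.0, "C": -1.0, "B": 1.0, "Cstar": 1.0}, 0.0,
                 1000.0, gpr=parse_gpr("g4"), subsystem="core"),
        Reaction("v5", {"B": -1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g5"), subsystem="core"),
        Reaction("v8", {"Cstar": -1.0, "C": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("g8"), subsystem="cofactor"),
    ]
    return MetabolicNetwork(mets, rxns, "v5")


def random_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Seeded random network with a guaranteed substrate-to-biomass path.

    Layout: an uptake ``u0: ext_S -> M0``, a linear backbone
    ``M0 -> M1 -> ... -> M_last`` ending in the biomass ``bio: M_last ->``,
    so FBA growth is positive on a medium supplying M0.  Each planted
    co-factor cycle claims a (CFk, CFk_star) pair, rewires one backbone step
    into ``Mi + CFk -> M(i+1) + CFk_star`` with a recycling reaction
    ``CFk_star -> CFk`` and, with probability one half, a biosynthesis branch
    ``Mj -> CFk``.  Remaining reaction slots are filled with random forward
    or reversible conversions between backbone metabolites.
    """
    rng = np.random.default_rng(spec.seed)
    n_cf = spec.n_cofactor_cycles
    n_chain = spec.n_internal_metabolites - 2 * n_cf
    chain = [f"M{i}" for i in range(n_chain)]
    cof = [(f"CF{k}", f"CF{k}_star") for k in range(n_cf)]
    mets = [Metabolite("ext_S", is_boundary=True)]
    mets += [Metabolite(m) for m in chain]
    for a, b in cof:
        mets.append(Metabolite(a, is_cofactor=True))
        mets.append(Metabolite(b, is_cofactor=True))

    rxns: List[Reaction] = [
        Reaction("u0", {"ext_S": -1.0, "M0": 1.0}, 0.0, 1000.0,
                 subsystem="exchange", is_exchange=True)
    ]
    backbone_steps = list(zip(chain[:-1], chain[1:]))
    cofactor_steps = set()
    if n_cf and len(backbone_steps) > 0:
        chosen = rng.choice(len(backbone_steps), size=min(n_cf, len(backbone_steps)),
                            replace=False)
        cofactor_steps = {int(i): k for k, i in enumerate(sorted(chosen))}
    for i, (a, b) in enumerate(backbone_steps):
        stoich = {a: -1.0, b: 1.0}
        if i in cofactor_steps:
            cf, cfs = cof[cofactor_steps[i]]
            stoich[cf] = -1.0
            stoich[cfs] = 1.0
        rxns.append(
            Reaction(f"r{i}", stoich, 0.0, 1000.0, subsystem="core")
        )
    for k, (cf, cfs) in enumerate(cof):
        rxns.append(
            Reaction(f"recycle{k}", {cfs: -1.0, cf: 1.0}, 0.0, 1000.0,
                     subsystem="cofactor")
        )
        if rng.random() < 0.5:
            src = chain[int(rng.integers(0, max(1, len(chain) - 1)))]
            rxns.append(
                Reaction(f"synth{k}", {src: -1.0, cf: 1.0}, 0.0, 1000.0,
                         subsystem="cofactor")
            )
    rxns.append(Reaction("bio", {chain[-1]: -1.0}, 0.0, 1000.0, subsystem="core"))

    extra = 0
    while len(rxns) < spec.n_reactions + 1:  # +1: uptake doesn't count a slot
        a, b = rng.choice(len(chain), size=2, replace=False)
        coeff = float(rng.integers(1, 3))
        reversible = bool(rng.random() < 0.3)
        rxns.append(
            Reaction(
                f"x{extra}",
                {chain[int(a)]: -coeff, chain[int(b)]: 1.0},
                -1000.0 if reversible else 0.0,
                1000.0,
                subsystem="misc",
            )
        )
        extra += 1
    for r in rxns:
        if r.gpr is None:
            r.gpr = parse_gpr(f"g_{r.id}")
    return MetabolicNetwork(mets, rxns, "bio")


def synthetic_phenotypes(
    network: MetabolicNetwork,
    conditions: Sequence[Condition],
    method: str = "MD-FBA",
    noise_sd: float = 0.1,
    seed: int = 0,
    config: Optional[MDFBAConfig] = None,
) -> pd.DataFrame:
    """Noisy measured growth proxies generated from a method's own predictions.

    measured = predicted mu x lognormal noise (sigma = ``noise_sd``), one row
    per condition with columns ``condition`` and ``value``.  Stands in for a
    phenotype-array table when testing the evaluation pipeline end to end.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, cond in enumerate(conditions):
        label = cond.label or f"condition_{i}"
        applied = apply_condition(network, cond)
        if method == "FBA":
            sol = solve_fba(applied)
            mu = sol.objective_value if sol.status == lp.OPTIMAL else 0.0
        else:
            msol = solve_mdfba(applied, config)
            mu = msol.growth
        noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
        rows.append({"condition": label, "value": float(mu) * noise})
    return pd.DataFrame(rows, columns=["condition", "value"])
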