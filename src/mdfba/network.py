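"""Metabolic network models, media and simulation conditions.

The central container is :class:`MetabolicNetwork`: an ordered collection of
metabolites and reactions with a designated biomass reaction.  Reversibility
is encoded purely by bounds (``lower_bound < 0``), never by splitting a
reaction, so the stoichiometric matrix keeps one column per model reaction.
Boundary metabolites (external pools, id prefix ``ext_`` in the tabular
dialect) are excluded from mass balance and never receive dilution variables
downstream.

Two on-disk formats are supported: SBML (read, via cobra/libsbml) and a small
tabular dialect for toy networks::

    id | equation            | lb | ub   | gpr        | subsystem
    v2 | 2 A -> D            | 0  | 1000 | g2         | core
    v4 | A + C <-> B + Cstar | -1000 | 1000 | gA or gB | core

``->`` forces ``lb = 0``; ``<->`` keeps the stated (reversible) bounds.
Columns may be separated by tabs or by ``|``.
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

from .gpr import GPRTree, evaluate_gpr, format_gpr, gpr_genes, parse_gpr

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0
BOUNDARY_PREFIX = "ext_"


class NetworkError(ValueError):
    """Raised for invalid networks, conditions or input files."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False
    is_cofactor: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRTree = None
    subsystem: str = ""
    is_exchange: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def gpr_string(self) -> str:
        return format_gpr(self.gpr)


@dataclass
class Medium:
    """Environmental nutrient limits: metabolite id -> max uptake rate.

    Metabolites not listed get zero allowed uptake.  Export is unrestricted
    (free secretion), matching the usual FBA convention.
    """

    uptake_limits: Dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for met, limit in self.uptake_limits.items():
            if limit < 0:
                raise NetworkError(f"negative uptake limit for {met!r}: {limit}")


@dataclass
class Condition:
    """One simulation scenario: a medium plus gene/reaction deletions."""

    medium: Medium
    deleted_genes: Set[str] = field(default_factory=set)
    deleted_reactions: Set[str] = field(default_factory=set)
    label: str = ""


@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings


class MetabolicNetwork:
    """Stoichiometric model: metabolites, reactions, biomass designation."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        biomass_reaction_id: str,
    ) -> None:
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self._index()
        self._check()

    # -- construction & invariants -------------------------------------------------

    def _index(self) -> None:
        self._met_by_id = {m.id: m for m in self.metabolites}
        self._rxn_by_id = {r.id: r for r in self.reactions}

    def _check(self) -> None:
        if len(self._met_by_id) != len(self.metabolites):
            raise NetworkError("duplicate metabolite ids")
        if len(self._rxn_by_id) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        for m in self.metabolites:
            if not m.id:
                raise NetworkError("empty metabolite id")
        for r in self.reactions:
            if not r.stoichiometry:
                raise NetworkError(f"reaction {r.id!r} has empty stoichiometry")
            for met, coeff in r.stoichiometry.items():
                if met not in self._met_by_id:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown metabolite {met!r}"
                    )
                if coeff == 0:
                    raise NetworkError(f"zero coefficient in reaction {r.id!r}")
        if self.biomass_reaction_id not in self._rxn_by_id:
            raise NetworkError(
                f"biomass reaction {self.biomass_reaction_id!r} not in network"
            )

    # -- lookups -------------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_by_id[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_by_id[rxn_id]

    @property
    def biomass_reaction(self) -> Reaction:
        return self._rxn_by_id[self.biomass_reaction_id]

    @property
    def internal_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions:
            out |= gpr_genes(r.gpr)
        return out

    def reactions_of(self, met_id: str) -> List[Reaction]:
        """R_j: reactions in which the metabolite participates."""
        return [r for r in self.reactions if met_id in r.stoichiometry]

    def stoichiometric_matrix(self) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
        """Sparse S over internal metabolites x reactions, plus row/col ids."""
        rows = [m.id for m in self.internal_metabolites]
        cols = [r.id for r in self.reactions]
        ridx = {m: i for i, m in enumerate(rows)}
        data, ii, jj = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                i = ridx.get(met)
                if i is not None:
                    ii.append(i)
                    jj.append(j)
                    data.append(coeff)
        S = sparse.csr_matrix((data, (ii, jj)), shape=(len(rows), len(cols)))
        return S, rows, cols

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [copy.deepcopy(m) for m in self.metabolites],
            [copy.deepcopy(r) for r in self.reactions],
            self.biomass_reaction_id,
        )

    # -- exchange semantics --------------------------------------------------------

    def exchange_metabolite(self, rxn: Reaction) -> Tuple[str, int]:
        """The internal metabolite moved by an exchange, and its import sign.

        Returns ``(metabolite_id, direction)`` where direction ``+1`` means a
        positive flux imports the metabolite (uptake written as
        ``ext_A -> A`` or ``-> A``) and ``-1`` means a negative flux does
        (cobra-style ``A ->``).
        """
        internal = {
            met: c
            for met, c in rxn.stoichiometry.items()
            if not self._met_by_id[met].is_boundary
        }
        if len(internal) != 1:
            raise NetworkError(
                f"exchange reaction {rxn.id!r} must move exactly one internal "
                f"metabolite, has {sorted(internal)}"
            )
        (met, coeff), = internal.items()
        return met, (1 if coeff > 0 else -1)


# ---------------------------------------------------------------------------------
# Equation parsing / formatting (tabular dialect)
# ---------------------------------------------------------------------------------

_ARROW = re.compile(r"<->|<=>|-->|->")


def parse_equation(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 A -> D"`` into net stoichiometry and a reversibility flag.

    Left-hand species get negative coefficients, right-hand positive;
    duplicates are summed and exact cancellations dropped.
    """
    m = _ARROW.search(text)
    if not m:
        raise NetworkError(f"no arrow in equation {text!r}")
    reversible = m.group(0) in ("<->", "<=>")
    lhs, rhs = text[: m.start()], text[m.end():]
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise NetworkError(f"empty term in equation {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise NetworkError(
                        f"bad coefficient {parts[0]!r} in equation {text!r}"
                    ) from exc
                met = parts[1]
            else:
                raise NetworkError(f"bad term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise NetworkError(f"equation {text!r} has net-zero stoichiometry")
    return stoich, reversible


def _fmt_coeff(x: float) -> str:
    return f"{x:g}"


def format_equation(stoich: Dict[str, float], reversible: bool) -> str:
    """Canonical equation text: metabolites sorted within each side."""
    lhs = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(stoich.items()) if c > 0]

    def side(terms):
        return " + ".join(
            m if c == 1 else f"{_fmt_coeff(c)} {m}" for m, c in terms
        )

    arrow = "<->" if reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------------

def _split_row(line: str) -> List[str]:
    fields = line.split("\t") if "\t" in line else line.split("|")
    return [f.strip() for f in fields]


def load_network_tabular(
    reactions_path,
    biomass_id: str,
    cofactor_list: Iterable[str] = (),
    boundary_ids: Iterable[str] = (),
) -> MetabolicNetwork:
    """Load a network from the tabular dialect.

    Species whose id starts with ``ext_`` (or listed in ``boundary_ids``) are
    boundary pools excluded from mass balance.  A non-biomass reaction that
    touches a boundary species, or whose stoichiometry names a single
    metabolite, is flagged as an exchange.
    """
    boundary_ids = set(boundary_ids)
    reactions: List[Reaction] = []
    met_ids: List[str] = []
    seen: Set[str] = set()
    with open(reactions_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if fields[0].lower() == "id":  # header
                continue
            if len(fields) < 4:
                raise NetworkError(
                    f"{reactions_path}:{lineno}: expected at least 4 columns "
                    f"(id, equation, lb, ub), got {len(fields)}"
                )
            rid, equation = fields[0], fields[1]
            try:
                lb, ub = float(fields[2]), float(fields[3])
                stoich, reversible = parse_equation(equation)
            except NetworkError as exc:
                raise NetworkError(f"{reactions_path}:{lineno}: {exc}") from exc
            if not reversible:
                lb = max(lb, 0.0)
            gpr = parse_gpr(fields[4]) if len(fields) > 4 else None
            subsystem = fields[5] if len(fields) > 5 else ""
            reactions.append(
                Reaction(rid, stoich, lb, ub, gpr=gpr, subsystem=subsystem)
            )
            for met in stoich:
                if met not in seen:
                    seen.add(met)
                    met_ids.append(met)
    metabolites = [
        Metabolite(
            mid,
            is_boundary=mid.startswith(BOUNDARY_PREFIX) or mid in boundary_ids,
            is_cofactor=mid in set(cofactor_list),
        )
        for mid in met_ids
    ]
    boundary = {m.id for m in metabolites if m.is_boundary}
    for r in reactions:
        if r.id == biomass_id:
            continue
        internal = [m for m in r.stoichiometry if m not in boundary]
        touches_boundary = len(internal) < len(r.stoichiometry)
        if touches_boundary or len(r.stoichiometry) == 1:
            r.is_exchange = True
    return MetabolicNetwork(metabolites, reactions, biomass_id)


def write_network_tabular(network: MetabolicNetwork, path) -> None:
    """Write the tabular dialect with canonical ordering/formatting.

    Write -> read -> write round-trips byte-identically.
    """
    with open(path, "w") as handle:
        handle.write("id\tequation\tlb\tub\tgpr\tsubsystem\n")
        for r in network.reactions:
            handle.write(
                "\t".join(
                    [
                        r.id,
                        format_equation(r.stoichiometry, r.reversible),
                        _fmt_coeff(r.lower_bound),
                        _fmt_coeff(r.upper_bound),
                        r.gpr_string,
                        r.subsystem,
                    ]
                )
                + "\n"
            )


def load_medium_tsv(path) -> Medium:
    """Read a medium file: TSV of (metabolite-id, max-uptake)."""
    limits: Dict[str, float] = {}
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if fields[0].lower() in ("metabolite", "id"):
                continue
            limits[fields[0]] = float(fields[1])
    import os

    return Medium(limits, name=os.path.basename(str(path)))


def load_conditions_tsv(path, media_dir=None) -> List[Condition]:
    """Read a condition table: TSV of (label, medium-file, deleted genes).

    Deleted genes are comma-separated; medium paths resolve relative to
    ``media_dir`` (default: the table's own directory).
    """
    import os

    base = media_dir if media_dir is not None else os.path.dirname(str(path))
    conditions: List[Condition] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if fields[0].lower() == "label":
                continue
            label, medium_file = fields[0], fields[1]
            genes = set()
            if len(fields) > 2 and fields[2]:
                genes = {g.strip() for g in fields[2].split(",") if g.strip()}
            medium = load_medium_tsv(os.path.join(base, medium_file))
            conditions.append(Condition(medium, deleted_genes=genes, label=label))
    return conditions


# ---------------------------------------------------------------------------------
# SBML I/O (via cobra)
# ---------------------------------------------------------------------------------

def load_network_sbml(path, biomass_id: Optional[str] = None) -> MetabolicNetwork:
    """Load an SBML model (Level 2/3) through cobra.

    The biomass reaction is taken from ``biomass_id`` if given, otherwise from
    the model's objective.  Reactions without explicit bounds get cobra's
    conventional defaults (±1000).
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    if biomass_id is None:
        objective = [
            r.id for r in model.reactions if r.objective_coefficient
        ]
        if len(objective) != 1:
            raise NetworkError(
                f"cannot identify a unique biomass reaction in {path}; "
                "pass biomass_id explicitly"
            )
        biomass_id = objective[0]
    metabolites = [
        Metabolite(
            m.id,
            name=m.name or "",
            compartment=m.compartment or "",
            is_boundary=bool(getattr(m, "boundary_condition", False))
            or m.id.startswith(BOUNDARY_PREFIX),
        )
        for m in model.metabolites
    ]
    reactions = []
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        reactions.append(
            Reaction(
                r.id,
                stoich,
                float(r.lower_bound),
                float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule),
                subsystem=getattr(r, "subsystem", "") or "",
                is_exchange=r.boundary and r.id != biomass_id,
            )
        )
    return MetabolicNetwork(metabolites, reactions, biomass_id)


def to_cobra(network: MetabolicNetwork, model_id: str = "model"):
    """Convert to a cobra model (boundary species dropped; exchanges become
    one-sided reactions, the usual SBML/cobra convention)."""
    import cobra

    model = cobra.Model(model_id)
    mets = {}
    for m in network.internal_metabolites:
        cm = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in network.reactions:
        cr = model.reactions.get_by_id(r.id)
        cr.add_metabolites(
            {mets[m]: c for m, c in r.stoichiometry.items() if m in mets}
        )
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr_string
    model.objective = network.biomass_reaction_id
    return model


# ---------------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------------

def apply_condition(
    network: MetabolicNetwork, condition: Condition
) -> MetabolicNetwork:
    """Return a copy of the network with a condition's medium and deletions applied.

    Medium: each exchange reaction's import capacity is set to the medium's
    uptake limit for its metabolite (zero if absent), clamped so bounds never
    widen; the export direction is left open.  Deletions: reactions whose GPR
    evaluates false under the deleted genes, and explicitly deleted reactions,
    get both bounds set to zero.  Idempotent for a fixed condition.
    """
    limits = condition.medium.uptake_limits
    importable = {}
    out = network.copy()
    for rxn in out.exchange_reactions:
        met, direction = out.exchange_metabolite(rxn)
        importable.setdefault(met, []).append((rxn, direction))
    unknown = [m for m in limits if m not in importable]
    if unknown:
        raise NetworkError(
            f"medium metabolites with no importing exchange reaction: {sorted(unknown)}"
        )
    for met, entries in importable.items():
        limit = limits.get(met, 0.0)
        for rxn, direction in entries:
            if direction > 0:
                rxn.upper_bound = min(rxn.upper_bound, limit)
                rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
            else:
                rxn.lower_bound = max(rxn.lower_bound, -limit)
                rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
    unknown_rxns = condition.deleted_reactions - {r.id for r in out.reactions}
    if unknown_rxns:
        raise NetworkError(f"deleted reactions not in model: {sorted(unknown_rxns)}")
    for rxn in out.reactions:
        dead = rxn.id in condition.deleted_reactions or (
            rxn.gpr is not None
            and not evaluate_gpr(rxn.gpr, condition.deleted_genes)
        )
        if dead:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------------
# Scope (network expansion)
# ---------------------------------------------------------------------------------

_FLUX_EPS = 1e-9


def compute_scope(
    network: MetabolicNetwork, seed_metabolite_ids: Iterable[str]
) -> Set[str]:
    """Producibility scope of a seed set by iterative network expansion.

    Starting from the seeds, repeatedly fire any reaction direction (forward
    if ``ub > 0``, backward if ``lb < 0``) whose internal substrates are all
    in the current set, adding its internal products; reversible reactions
    contribute both directions, so the scope over-approximates producibility.
    Reactions with no internal substrate (pure uptakes) never fire on their
    own — medium availability enters through the seeds.
    """
    boundary = {m.id for m in network.metabolites if m.is_boundary}
    scope: Set[str] = {s for s in seed_metabolite_ids if s not in boundary}
    directions = []
    for r in network.reactions:
        for sign, open_ in ((+1, r.upper_bound > _FLUX_EPS),
                            (-1, r.lower_bound < -_FLUX_EPS)):
            if not open_:
                continue
            subs = {
                m for m, c in r.stoichiometry.items()
                if sign * c < 0 and m not in boundary
            }
            prods = {
                m for m, c in r.stoichiometry.items()
                if sign * c > 0 and m not in boundary
            }
            if subs:
                directions.append((subs, prods))
    changed = True
    while changed:
        changed = False
        for subs, prods in directions:
            if subs <= scope and not prods <= scope:
                scope |= prods
                changed = True
    return scope


def medium_seeds(network: MetabolicNetwork) -> Set[str]:
    """Internal metabolites importable through some open exchange.

    Intended for a network to which a condition has already been applied, so
    exchange bounds encode the medium.
    """
    seeds: Set[str] = set()
    for rxn in network.exchange_reactions:
        met, direction = network.exchange_metabolite(rxn)
        capacity = rxn.upper_bound if direction > 0 else -rxn.lower_bound
        if capacity > _FLUX_EPS:
            seeds.add(met)
    return seeds


# ---------------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------------

def validate_network(network: MetabolicNetwork) -> ValidationReport:
    """Structural checks; returns a report, never raises on warnings.

    Flags dangling metabolites, inverted bounds, and biomass precursors that
    no reaction chain can produce even with every exchange open.
    """
    report = ValidationReport()
    used: Set[str] = set()
    for r in network.reactions:
        used |= set(r.stoichiometry)
        if r.lower_bound > r.upper_bound:
            report.errors.append(
                f"reaction {r.id}: inverted bounds "
                f"({r.lower_bound} > {r.upper_bound})"
            )
    for m in network.metabolites:
        if m.id not in used:
            report.warnings.append(f"metabolite {m.id}: participates in no reaction")
    all_seeds = medium_seeds(network)
    scope = compute_scope(network, all_seeds)
    biomass = network.biomass_reaction
    boundary = {m.id for m in network.metabolites if m.is_boundary}
    for met, coeff in biomass.stoichiometry.items():
        if coeff < 0 and met not in boundary and met not in scope:
            report.warnings.append(
                f"biomass precursor {met}: unproducible from any medium"
            )
    return report
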