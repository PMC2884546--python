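"""Condition-grid screening and evaluation statistics.

Screens a model over conditions (medium x deletions) with FBA and/or MD-FBA,
computes gene-essentiality growth profiles, and evaluates predictions against
measurements with the field's standard statistics: ROC/AUC on essentiality
(essential = positive class, low predicted growth = positive call), Spearman
correlation of predicted growth versus a measured proxy per strain, and a
paired Wilcoxon signed-rank comparison of two methods' correlation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import lp
from .fba import minimize_total_flux, solve_fba
from .mdfba import MDFBAConfig, activity_pattern, solve_mdfba
from .network import Condition, MetabolicNetwork, Medium, apply_condition

logger = logging.getLogger(__name__)

FBA = "FBA"
MD_FBA = "MD-FBA"
WILD_TYPE_KEY = "wild_type"


@dataclass
class GrowthMatrix:
    """Growth-rate predictions: conditions x methods, with per-cell status."""

    values: pd.DataFrame
    status: pd.DataFrame


def _solve_growth(
    network: MetabolicNetwork, method: str, config: Optional[MDFBAConfig]
) -> Tuple[float, str]:
    if method == FBA:
        sol = solve_fba(network)
        mu = sol.objective_value
    elif method == MD_FBA:
        sol = solve_mdfba(network, config)
        mu = sol.mu
    else:
        raise ValueError(f"unknown method {method!r}")
    if sol.status != lp.OPTIMAL:
        # infeasible or solver failure: recorded as zero growth with a flag
        return 0.0, sol.status
    return float(mu), sol.status


def growth_matrix(
    network: MetabolicNetwork,
    conditions: Sequence[Condition],
    methods: Sequence[str] = (FBA, MD_FBA),
    config: Optional[MDFBAConfig] = None,
) -> GrowthMatrix:
    """One solve per condition and method; failures isolated per cell."""
    labels = [c.label or f"condition_{i}" for i, c in enumerate(conditions)]
    values = pd.DataFrame(index=labels, columns=list(methods), dtype=float)
    status = pd.DataFrame(index=labels, columns=list(methods), dtype=object)
    for label, cond in zip(labels, conditions):
        try:
            applied = apply_condition(network, cond)
        except Exception as exc:  # bad condition: flag the whole row
            logger.warning("condition %s failed to apply: %s", label, exc)
            values.loc[label] = 0.0
            status.loc[label] = lp.ERROR
            continue
        for method in methods:
            try:
                mu, st = _solve_growth(applied, method, config)
            except Exception as exc:
                logger.warning("%s on %s failed: %s", method, label, exc)
                mu, st = 0.0, lp.ERROR
            values.loc[label, method] = mu
            status.loc[label, method] = st
        logger.info("condition %s done", label)
    return GrowthMatrix(values=values, status=status)


def essentiality_screen(
    network: MetabolicNetwork,
    gene_ids: Iterable[str],
    medium: Medium,
    method: str = MD_FBA,
    config: Optional[MDFBAConfig] = None,
) -> Tuple[Dict[str, float], List[str]]:
    """Growth rate per single-gene deletion on a fixed medium.

    Returns ``(results, unmapped)``: results maps each mappable gene to its
    predicted mu and includes the undeleted model under the reserved key
    ``wild_type``; genes absent from every GPR are returned in ``unmapped``
    and are not solved.
    """
    model_genes = network.genes
    results: Dict[str, float] = {}
    unmapped: List[str] = []
    wt, _ = _solve_growth(
        apply_condition(network, Condition(medium, label="wild_type")),
        method,
        config,
    )
    results[WILD_TYPE_KEY] = wt
    for gene in gene_ids:
        if gene not in model_genes:
            unmapped.append(gene)
            continue
        cond = Condition(medium, deleted_genes={gene}, label=gene)
        mu, _ = _solve_growth(apply_condition(network, cond), method, config)
        results[gene] = mu
    return results, unmapped


# ---------------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------------

def roc_auc(
    predicted_mu: Sequence[float], labels: Sequence[str]
) -> Tuple[float, np.ndarray]:
    """AUC of essentiality prediction from growth rates.

    ``labels`` are ``"essential"`` / ``"nonessential"``; essential is the
    positive class and the prediction score is ``-mu`` (lower growth = more
    essential), so the ROC sweeps a threshold on the predicted growth rate.
    The AUC equals the rank statistic: the probability that a random
    essential gene has lower predicted mu than a random nonessential one,
    ties counted half.  Returns ``(auc, points)`` with points an array of
    (FPR, TPR) rows.
    """
    y = np.asarray([1 if l == "essential" else 0 for l in labels])
    mu = np.asarray(predicted_mu, dtype=float)
    if len(y) != len(mu):
        raise ValueError("predicted_mu and labels differ in length")
    if y.min() == y.max():
        raise ValueError("labels contain a single class; AUC undefined")
    fpr, tpr, _ = _sk_roc_curve(y, -mu)
    return float(_sk_auc(fpr, tpr)), np.column_stack([fpr, tpr])


@dataclass
class MethodComparison:
    """Per-strain Spearman profiles of two methods and their paired test."""

    rho_a: pd.Series
    rho_b: pd.Series
    median_rho_a: float
    median_rho_b: float
    wilcoxon_p_two_sided: float
    wilcoxon_p_a_greater: float
    skipped_strains: List[str] = field(default_factory=list)


def _wilcoxon_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Paired signed-rank p-value: exact for n <= 25, else normal approx
    with continuity correction.  Identical vectors give p = 1."""
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    n = len(diff)
    method = "exact" if n <= 25 else "approx"
    try:
        res = stats.wilcoxon(
            a, b, alternative=alternative, method=method, correction=(method == "approx")
        )
    except ValueError:
        res = stats.wilcoxon(a, b, alternative=alternative, method="approx",
                             correction=True)
    return float(res.pvalue)


def compare_methods(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    measured: pd.DataFrame,
    min_points: int = 3,
) -> MethodComparison:
    """Compare two methods' growth predictions against measurements.

    All three frames are strains (rows) x media (columns).  For each strain a
    Spearman rho is computed between each method's predictions and the
    measured values; the two rho profiles are then compared with a paired
    Wilcoxon signed-rank test (both sidednesses reported).  Strains with
    fewer than ``min_points`` paired finite values are skipped and logged.
    """
    strains = measured.index.intersection(scores_a.index).intersection(scores_b.index)
    rho_a: Dict[str, float] = {}
    rho_b: Dict[str, float] = {}
    skipped: List[str] = []
    for strain in strains:
        cols = measured.columns.intersection(scores_a.columns).intersection(
            scores_b.columns
        )
        m = measured.loc[strain, cols].astype(float)
        a = scores_a.loc[strain, cols].astype(float)
        b = scores_b.loc[strain, cols].astype(float)
        mask = m.notna() & a.notna() & b.notna()
        if mask.sum() < min_points:
            skipped.append(str(strain))
            logger.info("strain %s skipped: %d paired points", strain, mask.sum())
            continue
        rho_a[strain] = _spearman(a[mask].values, m[mask].values)
        rho_b[strain] = _spearman(b[mask].values, m[mask].values)
    sa = pd.Series(rho_a, dtype=float)
    sb = pd.Series(rho_b, dtype=float)
    if len(sa) == 0:
        raise ValueError("no strain had enough paired points")
    return MethodComparison(
        rho_a=sa,
        rho_b=sb,
        median_rho_a=float(sa.median()),
        median_rho_b=float(sb.median()),
        wilcoxon_p_two_sided=_wilcoxon_p(sa.values, sb.values, "two-sided"),
        wilcoxon_p_a_greater=_wilcoxon_p(sa.values, sb.values, "greater"),
        skipped_strains=skipped,
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0  # constant vector: correlation undefined, report 0
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------------
# Activity differences
# ---------------------------------------------------------------------------------

def activity_difference_report(
    network: MetabolicNetwork,
    conditions: Sequence[Condition],
    config: Optional[MDFBAConfig] = None,
    flux_tol: Optional[float] = None,
) -> pd.DataFrame:
    """Mean per-subsystem count of reactions active under exactly one method.

    For each condition both methods are solved (FBA canonicalized by total-
    flux minimization at its optimum so alternate optima do not blur the
    pattern) and reactions in the symmetric difference of the two activity
    patterns are tallied by subsystem; unlabeled reactions group under
    ``unassigned``.  Columns: ``mdfba_only``, ``fba_only``, ``difference``
    (means across conditions).

    The default activity threshold sits just above epsilon: the MILP permits
    any reaction a sub-epsilon leak without tripping indicators, so fluxes at
    or below epsilon are below the formulation's activity resolution.
    """
    eps = (config or MDFBAConfig()).epsilon
    if flux_tol is None:
        flux_tol = max(1e-6, eps * (1.0 + 1e-6) + 1e-12)
    subsystems = sorted(
        {r.subsystem or "unassigned" for r in network.reactions}
    )
    counts = {
        s: {"mdfba_only": [], "fba_only": []} for s in subsystems
    }
    for cond in conditions:
        applied = apply_condition(network, cond)
        fba_sol = solve_fba(applied)
        if fba_sol.status == lp.OPTIMAL:
            canon = minimize_total_flux(applied, fba_sol.objective_value)
            fba_pattern = activity_pattern(
                canon if canon.status == lp.OPTIMAL else fba_sol, flux_tol
            )
        else:
            fba_pattern = set()
        md_sol = solve_mdfba(applied, config)
        md_pattern = (
            activity_pattern(md_sol, flux_tol)
            if md_sol.status == lp.OPTIMAL
            else set()
        )
        per_sub = {s: {"mdfba_only": 0, "fba_only": 0} for s in subsystems}
        for rid in md_pattern - fba_pattern:
            sub = network.reaction(rid).subsystem or "unassigned"
            per_sub[sub]["mdfba_only"] += 1
        for rid in fba_pattern - md_pattern:
            sub = network.reaction(rid).subsystem or "unassigned"
            per_sub[sub]["fba_only"] += 1
        for s in subsystems:
            counts[s]["mdfba_only"].append(per_sub[s]["mdfba_only"])
            counts[s]["fba_only"].append(per_sub[s]["fba_only"])
    rows = []
    for s in subsystems:
        md_only = float(np.mean(counts[s]["mdfba_only"])) if conditions else 0.0
        fba_only = float(np.mean(counts[s]["fba_only"])) if conditions else 0.0
        rows.append(
            {
                "subsystem": s,
                "mdfba_only": md_only,
                "fba_only": fba_only,
                "difference": md_only + fba_only,
            }
        )
    return pd.DataFrame(rows).set_index("subsystem")
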