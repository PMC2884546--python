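# Methods

## Model

A metabolic network is a stoichiometric matrix `S` (m internal metabolites ×
n reactions) with per-reaction flux bounds, an optional boolean
gene–protein–reaction (GPR) rule per reaction, and one designated biomass
pseudo-reaction whose flux is the growth rate μ (h⁻¹; fluxes in
mmol·gDW⁻¹·h⁻¹). Reversibility is encoded purely by a negative lower bound —
reactions are never split — so the matrix keeps one column per model
reaction. Boundary metabolites (external pools) are excluded from mass
balance. Exchange pseudo-reactions move one internal metabolite across the
boundary; a medium is a map from metabolite to maximal uptake rate, applied
by clamping each exchange's import capacity (`min(current bound, limit)`, so
condition application is idempotent and only ever tightens), with the export
direction left open. Gene deletions zero the bounds of every reaction whose
GPR evaluates false; reactions with an empty GPR are treated as spontaneous
and are never disabled.

## MD-FBA

Classic FBA solves `max μ s.t. S·v = 0, v_min ≤ v ≤ v_max`. MD-FBA replaces
the strict steady state with a balance that drains each *active* internal
metabolite at a growth-proportional dilution rate. Per internal metabolite j
the MILP carries `d_j ≥ 0` and a binary `y_j`:

* balance: `Σ_i S_ji v_i − d_j = 0`;
* indicators: every reaction able to produce j above the threshold ε trips
  `y_j = 1` (`v_i ≤ ε + (v_max,i − ε) y_j` for producing directions, and the
  mirror constraint for reversible consumers);
* dilution floor: `d_j ≥ ε·μ − M(1 − y_j)` with `M = ε·μ_max`, or `d_j ≥
  ε·y_j` in the simplified unit-growth mode.

The objective maximizes μ. Metabolites imported by an exchange count as
produced (an intracellular pool dilutes regardless of origin); biomass
precursors also carry dilution variables; `d_j` has no upper bound (a free
overflow sink). Boundary metabolites and metabolites appearing in no
reaction get no variables.

### Parameters

| parameter | default | meaning |
|---|---|---|
| ε | 1e-4 | activity threshold and dilution coefficient; corresponds to a typical intermediate-metabolite concentration (μmol/mg). ε·μ is used directly as the dilution flux floor. ε = 0 is accepted as a degenerate setting that relaxes MD-FBA to FBA (all dilution demands vanish). |
| coupling mode | μ-coupled | `d_j ≥ ε·μ`; the `unit_mu` mode uses `d_j ≥ ε` (growth fixed at 1 in the dilution term) and yields the same qualitative activity patterns on the bundled examples |
| μ_max | 1000 | growth cap; sets the dilution big-M. The effective cap is `min(μ_max, biomass upper bound)` |
| MILP gap | 1e-6 | relative optimality gap requested from the solver |
| default flux bound | ±1000 | conventional cap for otherwise unbounded reactions; keeps every big-M finite |

The formulation is only meaningful in the `ε·μ < 1` regime; the
configuration warns outside it.

### Numerical choices

All LPs and MILPs are solved with HiGHS (via `scipy.optimize.milp`), which
is deterministic for a fixed input. Two choices matter for correctness and
were both caught by the brute-force oracle on random fixtures:

* The dilution rows are stated divided through by ε (`d_j/ε ≥ μ − μ_max(1 −
  y_j)`), so the floor is O(μ) rather than O(ε·μ). In the raw scaling an
  optimum of order ε slips entirely under the solver's feasibility
  tolerance.
* Primal/dual/integrality tolerances are tightened to 1e-9: at the default
  integrality tolerance (1e-6) a nominally-zero binary times a bound of 1000
  leaks up to 1e-3 through an indicator cap.

Indicator semantics at the boundary are non-strict: a flux of exactly ε may
leave `y_j = 0` (a MILP cannot encode strict inequalities). Consequently an
"all-inactive" network can still carry fluxes up to ε, and every zero-growth
statement holds at that resolution: on a futile-cycle network the exact
MD-FBA optimum is μ = ε, not 0. Reactions confined to internal loops with no
production route are therefore starved to `|v| ≤ ε` rather than exactly
zero; activity comparisons between methods use a threshold just above ε.

Because dilution is a free sink, MD-FBA optima are degenerate in flux space
(e.g. surplus uptake routed straight to dilution). `solve_mdfba` therefore
canonicalizes by default: with the activity assignment and optimal μ fixed,
it minimizes total absolute flux, making reported fluxes deterministic and
parsimonious. The raw MILP vertex is available with `parsimonious=False`.
FBA activity patterns are canonicalized the same way (`minimize_total_flux`
at the FBA optimum) before comparing methods.

### Scope reduction

The producibility scope of a medium — the fixed point of network expansion
from the importable metabolites, firing any reaction direction whose
internal substrates are all already producible — over-approximates what can
ever be synthesized. Metabolites outside the scope can never satisfy a
dilution demand, so with scope reduction enabled they get no binary: their
indicator is fixed to 0 and their producing fluxes are capped at ε. This
shrinks the MILP without changing its optimum (verified on the bundled
networks). Reversible reactions contribute both directions to the expansion;
source-free reactions (pure uptakes) never fire on their own — availability
enters through the seeds.

### Verification oracle

`brute_force_mdfba` enumerates all 2^m activity assignments (refusing m >
14); for each, the indicator caps become plain bound tightenings and the
dilution floors plain linear constraints, leaving an LP. The best feasible
optimum over all assignments is the exact MD-FBA optimum by construction.
The MILP path is required to match it to 1e-6 on a corpus of seeded random
networks; the oracle is deliberately kept free of the MILP machinery.

## Biomass co-factor reduction

A co-factor fixed in the biomass imposes its synthesis everywhere, which
turns into false lethality on media where it is unproducible. Candidates are
each tested independently against the original biomass: the candidate's
coefficient is zeroed on a copy, MD-FBA is solved per supplied condition,
and dilution above 1e-8 (above solver noise, far below ε·μ) at the optimum
flags a dynamically predicted demand. Candidates flagged in at least one
condition (configurable quorum) are then removed jointly, making the outcome
independent of candidate order. The tested conditions are user-supplied; no
default strain sampling is performed.

## Evaluation statistics

Essentiality is scored as −μ (lower predicted growth = more essential call),
with the experimentally essential class positive; the ROC is the threshold
sweep on predicted growth and its AUC equals the essential×nonessential
pair-count rank statistic with half-credit ties (asserted in tests against
an exhaustive counter). Method-versus-method comparison computes, per
strain, the Spearman correlation between predicted growth and a measured
proxy across media, then compares the two correlation profiles with a paired
Wilcoxon signed-rank test — exact distribution for ≤ 25 pairs, normal
approximation with continuity correction above, both one- and two-sided
p-values reported. Strains with fewer than three paired observations are
skipped and logged. Dataset-specific filters (dropping no-growth media or
media on which methods agree above a correlation cutoff) are left to the
caller rather than applied by default.

## Synthetic data

The fixture generators define the conditions the tests probe:

* the eight-reaction example network (fixed, no seed): two routes to the
  biomass precursor, one requiring a recycled co-factor pair with a de novo
  synthesis branch from a second nutrient; uptake bounds of 1 (growth
  substrate) and 10 (co-factor precursor) via the media files;
* a futile-cycle variant keeping only the co-factor-dependent route and the
  recycling reaction;
* seeded random networks: a linear substrate→biomass backbone (guaranteeing
  FBA growth on the standard medium, uptake bound 10), planted co-factor
  cycles rewiring backbone steps (with a 50% chance of a biosynthesis
  branch), and random extra conversions, ~30% reversible — enough structural
  variety to exercise both indicator directions and infeasible dilution
  demands;
* synthetic phenotypes: a method's own predicted growth times lognormal
  noise (σ default 0.1), seeded.

These fixtures reproduce the *mechanisms* — catalytic cycles, context-
dependent co-factor demand, dilution-blocked growth — not the statistics of
genome-scale reconstructions (thousands of reactions, promiscuous
co-factors, maintenance reactions). Passing tests therefore demonstrate the
correctness of the formulation and pipeline, not expected predictive
performance on real models, which additionally depends on model curation and
measured data quality. Oracle-equivalence tests run at ≤ 12 internal
metabolites because exhaustive enumeration doubles per metabolite; growth
screens in tests use a handful of media and single-gene deletions.

## Known limitations

* The uniform dilution floor assumes one common concentration for all
  intermediate metabolites; per-metabolite concentration bounds are out of
  scope.
* Only biomass maximization is supported as an objective.
* Growth below ε is indistinguishable from zero (see numerical choices).
* SBML export is supported only for toy-scale models via the cobra
  converter; genome-scale SBML writing is out of scope, as are flux
  variability analysis and explicit thermodynamic loop-law constraints
  beyond what the dilution mechanism itself implies.
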