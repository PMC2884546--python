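"""The MD-FBA MILP: construction, solving, oracle equivalence, invariants."""

import pytest

from mdfba import (
    Condition,
    FixtureSpec,
    MDFBAConfig,
    Medium,
    activity_pattern,
    apply_condition,
    brute_force_mdfba,
    build_mdfba_problem,
    check_solution,
    compute_scope,
    figure1_network,
    futile_cycle_network,
    minimize_total_flux,
    random_network,
    solve_fba,
    solve_mdfba,
)
from mdfba.mdfba import MU_COUPLED, UNIT_MU


def _random_condition_net(seed):
    n_cof = seed % 3
    n_int = max(5 + (seed % 5), 2 + 2 * n_cof + 1)
    spec = FixtureSpec(
        seed=seed,
        n_internal_metabolites=n_int,
        n_reactions=n_int + 3,
        n_cofactor_cycles=n_cof,
    )
    net = random_network(spec)
    return apply_condition(net, Condition(Medium({"M0": 10.0})))


class TestProblemStructure:
    def test_variable_counts_on_figure_network(self, fig1, config):
        problem = build_mdfba_problem(fig1, config)
        names = {v.name for v in problem.variables}
        binaries = {v.name for v in problem.variables if v.integer}
        assert binaries == {f"y[{m}]" for m in ("A", "B", "C", "Cstar", "D", "X")}
        assert {f"d[{m}]" for m in ("A", "B", "C", "Cstar", "D", "X")} <= names
        balance_rows = [c for c in problem.constraints if c.name.startswith("balance")]
        assert len(balance_rows) == 6

    def test_no_internal_metabolites_reduces_to_fba(self, config):
        from mdfba import MetabolicNetwork, Metabolite, Reaction

        net = MetabolicNetwork(
            [Metabolite("ext_A", is_boundary=True), Metabolite("ext_B", is_boundary=True)],
            [Reaction("t", {"ext_A": -1.0, "ext_B": 1.0}, 0.0, 5.0)],
            "t",
        )
        problem = build_mdfba_problem(net, config)
        assert all(not v.integer for v in problem.variables)
        assert not problem.constraints
        sol = solve_mdfba(net, config)
        assert sol.mu == pytest.approx(5.0)

    def test_scope_reduction_restricts_binaries(self, fig1_a):
        config = MDFBAConfig(use_scope_reduction=True)
        problem = build_mdfba_problem(fig1_a, config)
        binaries = {v.name for v in problem.variables if v.integer}
        assert binaries == {"y[A]", "y[D]", "y[B]"}

    def test_scope_reduction_preserves_optimum(self, fig1_a, fig1_ax):
        plain = MDFBAConfig()
        reduced = MDFBAConfig(use_scope_reduction=True)
        for net in (fig1_a, fig1_ax):
            mu_plain = solve_mdfba(net, plain).mu
            mu_reduced = solve_mdfba(net, reduced).mu
            assert mu_reduced == pytest.approx(mu_plain, abs=1e-8)


class TestFigureNetwork:
    def test_growth_ratio_with_cofactor_precursor_available(self, fig1_ax, config):
        sol = solve_mdfba(fig1_ax, config)
        assert sol.status == "optimal"
        assert round(sol.mu / sol.fluxes["v1"], 3) == 1.000
        # de novo co-factor synthesis is on
        assert sol.fluxes["v6"] > 1e-6
        assert sol.fluxes["v7"] > 1e-6

    def test_growth_halves_without_cofactor_precursor(self, fig1_a, config):
        sol = solve_mdfba(fig1_a, config)
        assert round(sol.mu / sol.fluxes["v1"], 3) == 0.500
        # the efficient cycle is off (sub-threshold at most)
        assert abs(sol.fluxes["v4"]) <= config.epsilon + 1e-9
        assert abs(sol.fluxes["v8"]) <= config.epsilon + 1e-9

    def test_solution_contracts_hold(self, fig1_ax, fig1_a, config):
        for net in (fig1_ax, fig1_a):
            sol = solve_mdfba(net, config)
            assert check_solution(net, sol, config) == []

    def test_activity_pattern_versus_fba(self, fig1_ax, config):
        md = solve_mdfba(fig1_ax, config)
        md_pattern = activity_pattern(md)
        assert {"v1", "v4", "v5", "v6", "v7", "v8"} <= md_pattern
        assert "v2" not in md_pattern and "v3" not in md_pattern
        fba = minimize_total_flux(fig1_ax, solve_fba(fig1_ax).objective_value)
        assert md_pattern ^ activity_pattern(fba) == {"v6", "v7"}

    def test_all_zero_solution_has_empty_pattern(self, fig1):
        closed = apply_condition(fig1, Condition(Medium({})))
        sol = solve_mdfba(closed)
        assert activity_pattern(sol) == set()

    @pytest.mark.filterwarnings("ignore:epsilon")
    @pytest.mark.parametrize("eps", [1e-6, 1e-5, 1e-4, 1e-3])
    def test_media_ratios_robust_to_epsilon(self, fig1_ax, fig1_a, eps):
        config = MDFBAConfig(epsilon=eps)
        r_ax = solve_mdfba(fig1_ax, config)
        r_a = solve_mdfba(fig1_a, config)
        assert r_ax.mu / r_ax.fluxes["v1"] == pytest.approx(1.0, rel=0.01)
        assert r_a.mu / r_a.fluxes["v1"] == pytest.approx(0.5, rel=0.01)

    def test_unit_mu_mode_gives_same_qualitative_pattern(self, fig1_ax, fig1_a):
        for net in (fig1_ax, fig1_a):
            coupled = solve_mdfba(net, MDFBAConfig(coupling_mode=MU_COUPLED))
            unit = solve_mdfba(net, MDFBAConfig(coupling_mode=UNIT_MU))
            tol = 1e-3  # compare above the dilution-flux scale
            assert activity_pattern(coupled, tol) == activity_pattern(unit, tol)


class TestFutileCycle:
    def test_fba_grows_mdfba_does_not(self, config):
        net = apply_condition(
            futile_cycle_network(), Condition(Medium({"A": 1.0}))
        )
        assert solve_fba(net).objective_value == pytest.approx(1.0)
        sol = solve_mdfba(net, config)
        # growth collapses to the sub-threshold leak the linearization allows
        assert sol.mu <= config.epsilon + 1e-9

    def test_cycle_fluxes_confined_below_epsilon(self, config):
        net = apply_condition(
            futile_cycle_network(), Condition(Medium({"A": 1.0}))
        )
        sol = solve_mdfba(net, config)
        for rid in ("v4", "v8"):
            assert abs(sol.fluxes[rid]) <= config.epsilon + 1e-9


class TestBruteForceOracle:
    def test_figure_network_matches(self, fig1_a, config):
        exact = brute_force_mdfba(fig1_a, config)
        milp = solve_mdfba(fig1_a, config)
        assert milp.mu == pytest.approx(exact.mu, abs=1e-6)

    def test_single_metabolite_network(self, config):
        from mdfba import MetabolicNetwork, Metabolite, Reaction

        net = MetabolicNetwork(
            [Metabolite("ext_A", is_boundary=True), Metabolite("A")],
            [
                Reaction("up", {"ext_A": -1.0, "A": 1.0}, 0.0, 2.0,
                         is_exchange=True),
                Reaction("bio", {"A": -1.0}, 0.0, 1000.0),
            ],
            "bio",
        )
        exact = brute_force_mdfba(net, config)
        assert exact.mu == pytest.approx(solve_mdfba(net, config).mu, abs=1e-8)

    def test_refuses_oversized_networks(self, config):
        big = random_network(
            FixtureSpec(seed=9, n_internal_metabolites=16, n_reactions=18)
        )
        with pytest.raises(ValueError, match="brute force"):
            brute_force_mdfba(big, config)

    def test_all_inactive_assignment_caps_growth_at_epsilon(self, fig1_a, config):
        """With every indicator off, producing fluxes cap at eps, so mu <= eps."""
        exact = brute_force_mdfba(fig1_a, config)
        assert exact.mu > config.epsilon  # optimum uses active metabolites
        zero_net = fig1_a.copy()
        for r in zero_net.reactions:
            has_internal_product = any(
                c > 0 and not zero_net.metabolite(m).is_boundary
                for m, c in r.stoichiometry.items()
            )
            if has_internal_product:
                r.upper_bound = min(r.upper_bound, config.epsilon)
        sol = solve_fba(zero_net)
        assert sol.objective_value <= config.epsilon + 1e-12

    @pytest.mark.parametrize("seed", range(1, 9))
    def test_random_networks_match_oracle(self, seed, config):
        net = _random_condition_net(seed)
        milp = solve_mdfba(net, config)
        exact = brute_force_mdfba(net, config)
        assert milp.status == exact.status == "optimal"
        assert milp.mu == pytest.approx(exact.mu, abs=1e-6 * max(1, exact.mu))


class TestInvariants:
    def test_zero_epsilon_relaxes_to_fba(self, fig1_a, fig1_ax):
        """At eps = 0 every FBA solution is MD-FBA-feasible (all y=1, d=0)."""
        config = MDFBAConfig(epsilon=0.0)
        for net in (fig1_a, fig1_ax):
            fba_mu = solve_fba(net).objective_value
            md_mu = solve_mdfba(net, config).mu
            assert md_mu >= fba_mu - 1e-6

    def test_knockout_monotonicity(self, fig1, medium_ax, config):
        base = solve_mdfba(
            apply_condition(fig1, Condition(medium_ax)), config
        ).mu
        for gene in sorted(fig1.genes):
            cond = Condition(medium_ax, deleted_genes={gene})
            mu = solve_mdfba(apply_condition(fig1, cond), config).growth
            assert mu <= base + 1e-8

    def test_indicator_soundness_on_random_networks(self, config):
        for seed in (3, 5, 7):
            net = _random_condition_net(seed)
            sol = solve_mdfba(net, config)
            assert check_solution(net, sol, config) == []


class TestConfigValidation:
    def test_rejects_negative_epsilon(self):
        with pytest.raises(ValueError):
            MDFBAConfig(epsilon=-1e-4)

    def test_warns_outside_linearization_regime(self):
        with pytest.warns(UserWarning, match="mu_upper"):
            MDFBAConfig(epsilon=0.01, mu_upper=1000.0)

    def test_nonfinite_bounds_rejected(self, fig1, config):
        net = fig1.copy()
        net.reaction("v2").upper_bound = float("inf")
        with pytest.raises(ValueError, match="non-finite"):
            build_mdfba_problem(net, config)
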